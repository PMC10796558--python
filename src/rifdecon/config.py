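"""Run configuration.

Every tunable of the deconvolution pipeline lives here so that a run can be
reproduced from a single YAML file.  Defaults follow the published method
where it states a value (cubic B-splines, one coefficient per five samples,
first-derivative penalty, delay search bounded to +/-15 s) and are documented
package choices elsewhere (see docs/methods.md).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Conversion from internal perfusion units (mL blood per s per mL tissue,
#: i.e. s^-1) to the reported mL blood min^-1 (100 mL tissue)^-1.
PER_SECOND_TO_ML_MIN_100ML = 6000.0


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Settings for the Tikhonov deconvolution and downstream physiology.

    Parameters
    ----------
    spline_order : int
        B-spline order ``m``; 4 gives cubic splines with continuous first and
        second derivatives at the knots.
    k_divisor : int
        Number of interior knots is ``floor(n / k_divisor)`` for ``n`` time
        samples; the default 5 places roughly one knot per five seconds on a
        1-s grid.
    n_lambdas : int
        Number of log-spaced regularization weights on the L-curve grid.
    lambda_min_ratio : float
        Lower end of the lambda grid as a fraction of the largest singular
        value of the design matrix.
    lambda_max_ratio : float
        Upper end of the lambda grid as a multiple of the largest singular
        value.  With a seminorm penalty the relevant scale is the generalized
        singular spectrum of the (design, penalty) pair, which extends well
        beyond the design's largest singular value; the grid must reach the
        oversmoothing branch for the L-curve corner to be interior.
    nonneg_projection : bool
        If true, clip the recovered residue function at zero after solving
        (the base solver is unconstrained).
    curvature_window : int
        Stencil width (samples of the lambda grid) for the local quadratic
        fits used to evaluate L-curve curvature.
    delay_bounds_s : float
        Half-width of the arterial-delay search window (seconds).
    refine_step_s : float
        Step of the fine delay search after the 1-s grid pass.
    extra_points : int
        Samples appended past the tissue peak when fitting the delay kernel.
    tail_start_after_peak_s : float
        Extraction tail window starts at the later of peak time plus this
        offset and ``tail_min_fraction`` of the measured window.
    tail_min_fraction : float
        See above; fraction of the total window (default 0: the offset past
        the peak governs, so the fit uses the longest vascular-free stretch).
    tail_floor : float
        Residue samples below this fraction of the peak are excluded from
        the tail fit: at that depth a regularized solution carries mostly
        smoothing error and its logarithm would corrupt the line fit.
    trapping_threshold : float
        Tail decay rates below this (s^-1) are treated as trapping: the mean
        transit time diverges and the distribution volume is undefined.
    vd_return_fraction : float
        The integral-ratio distribution volume is used only when the tissue
        curve has decayed below this fraction of its peak by the end of the
        scan; otherwise vd = CBF x MTT.
    """

    spline_order: int = 4
    k_divisor: int = 5
    n_lambdas: int = 60
    lambda_min_ratio: float = 1e-8
    lambda_max_ratio: float = 1e4
    nonneg_projection: bool = False
    curvature_window: int = 5
    delay_bounds_s: float = 15.0
    refine_step_s: float = 0.1
    extra_points: int = 10
    tail_start_after_peak_s: float = 60.0
    tail_min_fraction: float = 0.0
    tail_floor: float = 1e-3
    trapping_threshold: float = 1e-4
    vd_return_fraction: float = 0.1
    mask_mad_factor: float = 3.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "DeconvolutionConfig":
        return dataclasses.replace(self, **kwargs)

    def config_hash(self) -> str:
        """Short stable hash used in output provenance sidecars."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "DeconvolutionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = DeconvolutionConfig()
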