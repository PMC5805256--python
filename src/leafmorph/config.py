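"""Run configuration.

All tunable constants of the pipeline live here.  The defaults are the
method's published operating point: five magnitude thresholds
{15, 25, 35, 45, 55} px for lobe/sinus detection, a small threshold of 2 px
for margin teeth, a normalised-angle split threshold of 0.5 for the
north/south regions, and a 15-degree CCG interval angle.  Distance-based
thresholds are in pixels at the working scale, so silhouettes are
standardised to a fixed longest side (512 px) before the signature is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass
class RunConfig:
    #: magnitude thresholds (px) for lobe/sinus extrema consolidation
    magnitude_thresholds: tuple[float, ...] = (15.0, 25.0, 35.0, 45.0, 55.0)
    #: small magnitude threshold (px) for margin teeth
    small_threshold: float = 2.0
    #: normalised vertex-angle split between north and south regions
    thres_norm: float = 0.5
    #: CCG interval angle theta (degrees); must divide 90
    ccg_interval: float = 15.0
    #: longest silhouette side after standardisation (px)
    standard_size: int = 512
    #: background padding kept around the silhouette (px)
    border_pad: int = 8
    #: normalise the signature to [0, 100] before thresholding (off: raw px)
    normalise_signature: bool = False
    #: tolerance on |A/B - 1| for "approximately equal" tooth flanks
    equal_tol: float = 0.2
    #: ripples-ratio tolerance below which a margin counts as entire
    entire_tol: float = 0.005
    #: disk radius for margin smoothing; None = incircle_radius / 8
    smoothing_radius: float | None = None
    #: tooth/midrib ratio below which teeth are diminutive
    diminutive_bound: float = 1.0 / 16.0
    #: tooth/midrib ratio above which an excursion is lobe-scale, not a tooth
    lobe_ratio_bound: float = 1.0 / 8.0
    #: proximity tolerance (fraction of contour length) when subtracting
    #: large-threshold extrema from small-threshold extrema
    teeth_match_tol: float = 0.01
    #: mode-mean ratio above which tooth sizes count as bimodal (doubly serrate)
    doubly_ratio: float = 1.8
    #: fewer measurable teeth than this counts as an entire margin
    min_teeth: int = 4
    #: contour fraction used for a pole region when no flanking minima exist
    pole_fallback_fraction: float = 1.0 / 8.0
    #: hard cap on a pole region, as a fraction of the contour
    region_cap_fraction: float = 0.25
    #: cap substituted for an infinite CCG gradient (vertical chord)
    gradient_cap: float = 1000.0
    #: cut off a narrow basal protrusion before analysis
    remove_petiole: bool = False
    #: neighbours consulted by the species matcher
    knn_k: int = 1
    #: seed for any stochastic step (jitter in synthetic data)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.magnitude_thresholds or any(
            t <= 0 for t in self.magnitude_thresholds
        ):
            raise ValueError("magnitude thresholds must be positive")
        if not 0.0 < self.thres_norm < 1.0:
            raise ValueError("thres_norm must lie in (0, 1)")
        if self.ccg_interval <= 0 or 90.0 % self.ccg_interval != 0:
            raise ValueError("ccg_interval must divide 90")

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    # -- flat key=value persistence (CLI config files) ---------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kw = {}
        ftypes = {f.name: f for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            raw = raw.split("#", 1)[0].strip()
            if not raw:
                continue
            key, _, val = raw.partition("=")
            key, val = key.strip(), val.strip()
            if key not in ftypes:
                raise KeyError(f"unknown config key: {key}")
            kw[key] = _parse(key, val)
        return cls(**kw)


def _parse(key: str, val: str):
    if key == "magnitude_thresholds":
        return tuple(float(x) for x in val.split(",") if x.strip())
    if val == "None":
        return None
    if val in ("True", "False"):
        return val == "True"
    if key in ("standard_size", "border_pad", "knn_k", "seed"):
        return int(val)
    return float(val)


DEFAULT_CONFIG = RunConfig()
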