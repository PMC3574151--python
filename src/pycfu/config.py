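"""Parameter containers and configuration file handling.

Every tunable constant of the pipeline lives in one of the dataclasses
below so that a single TOML file (or CLI flags) can override any of them.
Defaults for the particle-filter inequality constants were calibrated on
the synthetic fixture suite (clean discs, fused dumbbells, rings, bars,
cracks); they are implementation-chosen, not claims about any other
colony counter.
"""

from __future__ import annotations

import dataclasses
import io
import tomllib
from dataclasses import dataclass, field


@dataclass
class FilterParams:
    """Constants of the morphological particle filter.

    The filter is a three-stage cascade:

    1. *screen* — reject a component outright if its equivalent radius is
       below ``r_min``, its aspect ratio exceeds ``aspect_screen`` or its
       hollowness exceeds ``hollow_screen``.
    2. *single evidence* — a component is presumed to be one object if at
       least one of: circularity >= ``circ_single``; convexity >=
       ``conv_single`` together with aspect ratio <= ``aspect_single``;
       equivalent radius <= ``small_radius_factor * r_min``.
    3. *confirmation / cluster* — a presumed single must additionally
       satisfy all of: equivalent radius <= ``r_max``, convexity >=
       ``conv_confirm``, hollowness <= ``hollow_confirm``.  A component
       without single evidence is a cluster only if all of: hollowness <=
       ``hollow_multi``, aspect ratio <= ``aspect_multi``, convexity >=
       ``conv_multi`` and area >= ``2 * pi * r_min**2`` (room for at least
       two minimal objects).  Everything else is invalid.

    ``r_max=None`` means "derive from the image": ``min(height, width)/20``.
    """

    r_min: float = 3.0
    r_max: float | None = None

    # stage 1: screening (used during score-map accumulation as well)
    aspect_screen: float = 4.0
    hollow_screen: float = 0.35
    #: a screened region may be a fused cluster, so its radius can exceed
    #: r_max — but not by more than this factor; plate-spanning noise or
    #: background unions are rejected outright
    screen_rmax_factor: float = 2.0

    # stage 2: single-object evidence (any one suffices)
    circ_single: float = 0.90
    conv_single: float = 0.95
    aspect_single: float = 1.45
    small_radius_factor: float = 1.2

    # stage 3a: single-object confirmation (all required)
    conv_confirm: float = 0.85
    hollow_confirm: float = 0.15

    # stage 3b: cluster confirmation (all required)
    hollow_multi: float = 0.25
    aspect_multi: float = 4.0
    conv_multi: float = 0.55
    multi_min_objects: float = 2.0

    # watershed-fragment reassessment: a cut chord removes area while
    # keeping most of the perimeter, so fragments of a correct split sit
    # systematically below the full-disc circularity/convexity bars;
    # a wrongly unsplit pair still fails the aspect cap
    frag_circ: float = 0.62
    frag_conv: float = 0.75
    frag_aspect: float = 1.8

    def resolved_r_max(self, shape: tuple[int, int]) -> float:
        if self.r_max is not None:
            return float(self.r_max)
        return max(min(shape) / 20.0, self.r_min + 2.0)


@dataclass
class PreprocessParams:
    """Background estimation, contrast enhancement and channel merging."""

    median_radius: int | None = None  #: None -> ceil(r_max), so colonies survive
    log_sigma: float = 1.0            #: scale of the Laplacian-of-Gaussian, px
    log_gain: float = 2.0             #: weight of the positive-LoG self-subtraction
    polarity: str = "auto"            #: "bright", "dark" or "auto"
    #: zero foreground deviations below this multiple of the estimated
    #: pixel-noise sigma (MAD-based); prevents min-max normalisation from
    #: amplifying pure noise to full range on near-empty plates
    noise_floor: float = 3.0


@dataclass
class ScoremapParams:
    """Threshold sweep and score-map binarisation."""

    stride: int = 1            #: step between successive grey-level thresholds
    score_threshold: int = 12  #: votes needed to keep a pixel; <=0 means AUTO


@dataclass
class SegmentParams:
    """Chamfer transform and constrained-watershed splitting."""

    kappa_area: float = 1.3  #: region area limit = kappa_area * pi * peak**2
    #: marker-to-pixel geodesic distance limit = kappa_dist * peak; tight
    #: enough that a marker cannot wrap around a neck and strip the rim of
    #: the neighbouring colony, loose enough to claim its own full disc
    kappa_dist: float = 1.25
    nms_radius: float = 2.0  #: suppress maxima closer than this to a higher one
    #: additionally suppress maxima closer than this multiple of a higher
    #: peak's presumptive radius — two colony centres cannot be nearer than
    #: about one radius, but the centre of a compact cluster often is
    nms_peak_factor: float = 0.7
    #: 3x3 majority-filter passes applied to the thresholded score-map
    #: before labelling, to de-fuzz rims raggedised by pixel noise
    mask_smooth_iters: int = 1


@dataclass
class PostfilterParams:
    """Colour/intensity outlier exclusion."""

    enabled: bool = False
    quantile: float = 0.0   #: exclusion quantile in [0, 1); 0 excludes nothing
    sd_floor: float = 1e-3  #: lower bound on the fitted per-channel sd


@dataclass
class RoiParams:
    """Region-of-interest handling and automatic dish detection."""

    auto_petri: bool = False
    margin: int = -25          #: signed radius adjustment of the detected dish, px
    radius_frac: tuple[float, float] = (0.25, 0.55)
    #: minimum normalised accumulator to accept a circle; random edge
    #: alignments on structureless images reach ~0.4, real rims >= 0.7
    hough_threshold: float = 0.55


@dataclass
class PipelineConfig:
    """Aggregate configuration for an end-to-end run."""

    filter: FilterParams = field(default_factory=FilterParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    scoremap: ScoremapParams = field(default_factory=ScoremapParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    postfilter: PostfilterParams = field(default_factory=PostfilterParams)
    roi: RoiParams = field(default_factory=RoiParams)


_SECTIONS = {
    "filter": FilterParams,
    "preprocess": PreprocessParams,
    "scoremap": ScoremapParams,
    "segment": SegmentParams,
    "postfilter": PostfilterParams,
    "roi": RoiParams,
}


def load_config(path: str) -> PipelineConfig:
    """Read a TOML configuration file into a :class:`PipelineConfig`.

    Unknown sections or keys raise ``ValueError`` so that typos do not
    silently fall back to defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig()
    for section, values in raw.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section [{section}]")
        target = getattr(cfg, section)
        names = {f.name for f in dataclasses.fields(target)}
        for key, val in values.items():
            if key not in names:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            if key == "radius_frac":
                val = tuple(val)
            setattr(target, key, val)
    return cfg


def dump_config(cfg: PipelineConfig | None = None) -> str:
    """Render a configuration (defaults if none given) as TOML text."""
    cfg = cfg or PipelineConfig()
    buf = io.StringIO()
    for section in _SECTIONS:
        buf.write(f"[{section}]\n")
        for f in dataclasses.fields(getattr(cfg, section)):
            val = getattr(getattr(cfg, section), f.name)
            if val is None:
                buf.write(f"# {f.name} = (auto)\n")
            elif isinstance(val, bool):
                buf.write(f"{f.name} = {'true' if val else 'false'}\n")
            elif isinstance(val, tuple):
                buf.write(f"{f.name} = [{', '.join(str(v) for v in val)}]\n")
            elif isinstance(val, str):
                buf.write(f'{f.name} = "{val}"\n')
            else:
                buf.write(f"{f.name} = {val}\n")
        buf.write("\n")
    return buf.getvalue()
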