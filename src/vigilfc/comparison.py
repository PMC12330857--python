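"""Signed-map comparison statistics: multiclass Dice reproducibility and
signed Szymkiewicz-Simpson network-template overlap."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import SignedMap

BAND_CUTOFFS = (0.4, 0.6)  # poor < 0.4 <= moderate < 0.6 <= good


@dataclass
class NetworkTemplate:
    m: np.ndarray   # binary inclusion per target
    name: str

    def __post_init__(self):
        m = np.asarray(self.m).astype(bool)
        if not m.any():
            raise ValueError("template must include at least one target")
        self.m = m


@dataclass
class OverlapResult:
    coefficient: float
    template: str
    map_id: str


@dataclass
class DscResult:
    dsc: float
    band: str
    pair: tuple[str, str]


def _signs(obj) -> np.ndarray:
    if isinstance(obj, SignedMap):
        return np.asarray(obj.sign)
    return np.sign(np.asarray(obj)).astype(int)


def signed_overlap(signed_map, template: NetworkTemplate,
                   map_id: str = "map") -> OverlapResult:
    """sum_i sgn(t_i) * m_i / sum_i m_i, in [-1, 1].

    Thresholded-out targets contribute sign 0.  Positive values mean the
    map is mostly positive inside the template.
    """
    s = _signs(signed_map)
    if len(s) != len(template.m):
        raise ValueError("map and template must share the target index")
    denom = float(template.m.sum())
    return OverlapResult(float(s[template.m].sum() / denom),
                         template.name, map_id)


def multiclass_dsc(map_a, map_b, pair: tuple[str, str] = ("a", "b"),
                   mask: np.ndarray | None = None) -> DscResult:
    """Dice generalized to signed classes:
    2*(|A+ n B+| + |A- n B-|) / (|A+| + |B+| + |A-| + |B-|).

    Background (zero) targets do not form a class.  Two empty maps give
    0 with a warning.  When ``mask`` is given, maps are compared on that
    intersection only.
    """
    a, b = _signs(map_a), _signs(map_b)
    if len(a) != len(b):
        raise ValueError("maps must share the target index")
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        a, b = a[keep], b[keep]
    denom = float((a > 0).sum() + (b > 0).sum() + (a < 0).sum() + (b < 0).sum())
    if denom == 0:
        warnings.warn("both signed maps empty: DSC defined as 0")
        return DscResult(0.0, reproducibility_band(0.0), pair)
    inter = float(((a > 0) & (b > 0)).sum() + ((a < 0) & (b < 0)).sum())
    d = 2.0 * inter / denom
    return DscResult(d, reproducibility_band(d), pair)


def reproducibility_band(dsc: float) -> str:
    """poor (DSC < 0.4), moderate (0.4 <= DSC < 0.6), good (DSC >= 0.6)."""
    if not 0.0 <= dsc <= 1.0:
        raise ValueError("DSC must lie in [0, 1]")
    if dsc < BAND_CUTOFFS[0]:
        return "poor"
    if dsc < BAND_CUTOFFS[1]:
        return "moderate"
    return "good"
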