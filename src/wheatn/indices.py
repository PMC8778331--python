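"""Registry of nitrogen-sensitive vegetation indices for four sensors.

Four index families:

* ``asd`` — 28 narrow-band indices from full-range (350–2500 nm) canopy
  reflectance: simple ratios, normalized differences, soil-adjusted and
  chlorophyll-absorption indices, and three red-edge descriptors (REP, the
  reflectance at REP, and the maximal first derivative of the red edge).
* ``multiplex`` — 9 multi-excitation chlorophyll-fluorescence indices built
  from six raw channel signals (simple fluorescence ratios SFR, excitation
  ratios FER, log-ratio flavonol/anthocyanin proxies, and the fluorescence
  nitrogen balance indices NBI_G/NBI_R).
* ``rgb`` — 14 digital-camera indices from calibrated band DNs (bands scaled
  by 255, chromatic coordinates, excess-red/green and derived differences).
* ``dualex`` — 3 leaf-clip outputs (NBI, Chl, Flav) passed through as
  features.

Undefined values (zero denominators, logs of non-positive ratios) are
reported as ``NaN`` — missing data, never exceptions — so a single degenerate
plot cannot abort a run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wheatn.spectra import ReflectanceSpectrum, RGBPlotStats, band

logger = logging.getLogger(__name__)

ASD_RANGE = (350, 2500)
RED_EDGE_WINDOW = (680, 760)


@dataclass(frozen=True)
class FluorescenceReading:
    """Six raw fluorescence channel signals (arbitrary positive units).

    B/F/R prefixes: blue-green (BGF), far-red (FRF) and red (RF) fluorescence;
    the suffix names the excitation light (UV, green G, red R).
    """

    BGF_UV: float
    FRF_UV: float
    FRF_G: float
    RF_G: float
    FRF_R: float
    RF_R: float

    def __post_init__(self) -> None:
        for name in ("BGF_UV", "FRF_UV", "FRF_G", "RF_G", "FRF_R", "RF_R"):
            if not getattr(self, name) > 0:
                raise ValueError(f"fluorescence channel {name} must be positive")


@dataclass(frozen=True)
class DualexReading:
    """Leaf-clip sensor outputs: nitrogen balance index, chlorophyll, flavonols."""

    NBI: float
    Chl: float
    Flav: float

    def __post_init__(self) -> None:
        for name in ("NBI", "Chl", "Flav"):
            if not getattr(self, name) > 0:
                raise ValueError(f"Dualex reading {name} must be positive")


def _safe_div(num: float, den: float) -> float:
    if den == 0 or not math.isfinite(den) or not math.isfinite(num):
        return math.nan
    return num / den


def _nd(a: float, b: float) -> float:
    """Normalized difference (a − b)/(a + b)."""
    return _safe_div(a - b, a + b)


def _log10(x: float) -> float:
    if not (math.isfinite(x) and x > 0):
        return math.nan
    return math.log10(x)


def _sqrt(x: float) -> float:
    if not (math.isfinite(x) and x >= 0):
        return math.nan
    return math.sqrt(x)


# ---------------------------------------------------------------------------
# Red-edge descriptors
# ---------------------------------------------------------------------------


def red_edge_position(spectrum: ReflectanceSpectrum) -> float:
    """Red-edge position (nm) by 4-point linear interpolation.

    ``REP = 700 + 40 · ((R670 + R780)/2 − R700) / (R740 − R700)``; NaN when
    R740 = R700 (flat red edge).
    """
    r670, r700, r740, r780 = (band(spectrum, w) for w in (670, 700, 740, 780))
    return 700.0 + 40.0 * _safe_div((r670 + r780) / 2.0 - r700, r740 - r700)


def rep_reflectance(spectrum: ReflectanceSpectrum) -> float:
    """Reflectance value at the red-edge position (linear interpolation)."""
    rep = red_edge_position(spectrum)
    if not math.isfinite(rep) or not spectrum.wl_min <= rep <= spectrum.wl_max:
        return math.nan
    return band(spectrum, rep)


def red_edge_max_derivative(spectrum: ReflectanceSpectrum) -> float:
    """Maximum per-nm first difference of reflectance over 680–760 nm."""
    lo, hi = RED_EDGE_WINDOW
    if not spectrum.covers(lo, hi):
        raise ValueError("spectrum does not cover the 680-760 nm red-edge window")
    i0 = lo - spectrum.wl_min
    i1 = hi - spectrum.wl_min
    return float(np.max(np.diff(spectrum.values[i0 : i1 + 1])))


# ---------------------------------------------------------------------------
# ASD narrow-band index formulas (spectrum -> value)
# ---------------------------------------------------------------------------


def _asd_formulas(strict: bool = False):
    B = band  # local alias

    def tbi2(s):
        if strict:  # printed form is degenerate (identically 1)
            return _safe_div(B(s, 924) - B(s, 703), B(s, 924) - B(s, 703))
        return _nd(B(s, 924), B(s, 703))

    def mcari(s):
        return ((B(s, 700) - B(s, 670)) - 0.2 * (B(s, 700) - B(s, 550))) * _safe_div(
            B(s, 700), B(s, 670)
        )

    def tcari(s):
        return 3.0 * (
            (B(s, 700) - B(s, 670))
            - 0.2 * (B(s, 700) - B(s, 550)) * _safe_div(B(s, 700), B(s, 670))
        )

    def msavi(s):
        r800, r670 = B(s, 800), B(s, 670)
        return 0.5 * (2 * r800 + 1 - _sqrt((2 * r800 + 1) ** 2 - 8 * (r800 - r670)))

    def mcari2(s):
        r800, r670, r550 = B(s, 800), B(s, 670), B(s, 550)
        num = 1.5 * (2.5 * (r800 - r670) - 1.3 * (r800 - r550))
        den = _sqrt((2 * r800 + 1) ** 2 - (6 * r800 - 5 * _sqrt(r670)) - 0.5)
        return _safe_div(num, den)

    def rdvi(s):
        r800, r670 = B(s, 800), B(s, 670)
        return _safe_div(r800 - r670, _sqrt(r800 + r670))

    return {
        "SR_(700,670)": lambda s: _safe_div(B(s, 700), B(s, 670)),
        "SR_(418,450)": lambda s: _safe_div(B(s, 418), B(s, 450)),
        "VOGa": lambda s: _safe_div(B(s, 740), B(s, 720)),
        "SR_(553,537)": lambda s: _safe_div(B(s, 553), B(s, 537)),
        "NDCI": lambda s: _nd(B(s, 762), B(s, 527)),
        "NDRE": lambda s: _nd(B(s, 790), B(s, 720)),
        "TBI1": lambda s: _safe_div(B(s, 434), B(s, 496) + B(s, 401)),
        "mND705": lambda s: _safe_div(
            B(s, 750) - B(s, 705), B(s, 750) + B(s, 705) - 2 * B(s, 445)
        ),
        "NDIopt": lambda s: _nd(B(s, 503), B(s, 483)),
        "TBI2": tbi2,
        "NDVI_(670,780)": lambda s: _nd(B(s, 780), B(s, 670)),
        "RDVI": rdvi,
        "SR_(750,700)": lambda s: _safe_div(B(s, 750), B(s, 700)),
        "WI": lambda s: _safe_div(B(s, 900), B(s, 950)),
        "NDWI": lambda s: _nd(B(s, 860), B(s, 1240)),
        "NDII": lambda s: _nd(B(s, 819), B(s, 1600)),
        "MCARI": mcari,
        "TCARI": tcari,
        "OSAVI": lambda s: 1.16 * _safe_div(B(s, 800) - B(s, 670), B(s, 800) + B(s, 670) + 0.16),
        "MSAVI": msavi,
        "MCARI1": lambda s: 1.2 * (2.5 * (B(s, 800) - B(s, 670)) - 1.3 * (B(s, 800) - B(s, 550))),
        "MCARI2": mcari2,
        "PPR": lambda s: _nd(B(s, 550), B(s, 450)),
        "PVR": lambda s: _nd(B(s, 550), B(s, 650)),
        "PRI": lambda s: _nd(B(s, 531), B(s, 570)),
        "REP": red_edge_position,
        "REV": rep_reflectance,
        "REFD": red_edge_max_derivative,
    }


# aliases used interchangeably in the results literature (same band math)
ASD_ALIASES = {"SR_(418,405)": "SR_(418,450)", "SR_(740,720)": "VOGa"}

# ---------------------------------------------------------------------------
# Multiplex fluorescence index formulas (reading -> value)
# ---------------------------------------------------------------------------

MULTIPLEX_FORMULAS = {
    "SFR_G": lambda f: _safe_div(f.FRF_G, f.RF_G),
    "SFR_R": lambda f: _safe_div(f.FRF_R, f.RF_R),
    "BRR_FRF": lambda f: _safe_div(f.BGF_UV, f.FRF_UV),
    "FER_RUV": lambda f: _safe_div(f.FRF_R, f.FRF_UV),
    "FER_RG": lambda f: _safe_div(f.FRF_R, f.FRF_G),
    "FLAV": lambda f: _log10(_safe_div(f.FRF_R, f.FRF_UV)),
    "ANTH": lambda f: _log10(_safe_div(f.FRF_R, f.FRF_G)),
    "NBI_G": lambda f: _safe_div(f.FRF_UV, f.RF_G),
    "NBI_R": lambda f: _safe_div(f.FRF_UV, f.RF_R),
}

# ---------------------------------------------------------------------------
# RGB camera index formulas (calibrated band DNs -> value)
# ---------------------------------------------------------------------------


def _rgb_formulas():
    def chrom(dn):
        # bands scaled by 255, then chromatic coordinates r + g + b = 1
        R, G, B = dn["R"] / 255.0, dn["G"] / 255.0, dn["B"] / 255.0
        tot = R + G + B
        if tot == 0:
            return R, G, B, math.nan, math.nan, math.nan
        return R, G, B, R / tot, G / tot, B / tot

    return {
        "R": lambda dn: dn["R"] / 255.0,
        "G": lambda dn: dn["G"] / 255.0,
        "B": lambda dn: dn["B"] / 255.0,
        "r": lambda dn: chrom(dn)[3],
        "g": lambda dn: chrom(dn)[4],
        "b": lambda dn: chrom(dn)[5],
        "ExR": lambda dn: 1.4 * chrom(dn)[3] - chrom(dn)[5],
        "ExG": lambda dn: 2 * chrom(dn)[4] - (chrom(dn)[3] + chrom(dn)[5]),
        "NDI": lambda dn: _nd(chrom(dn)[5], chrom(dn)[4]),
        "CVI1": lambda dn: chrom(dn)[3] - chrom(dn)[4],
        "CVI2": lambda dn: chrom(dn)[4] - chrom(dn)[5],
        "CVI3": lambda dn: _safe_div(chrom(dn)[4] - chrom(dn)[5], chrom(dn)[3] - chrom(dn)[4]),
        "GRVI": lambda dn: _nd(chrom(dn)[4], chrom(dn)[3]),
        "NPCI": lambda dn: _nd(chrom(dn)[5], chrom(dn)[3]),
    }


RGB_FORMULAS = _rgb_formulas()

DUALEX_FEATURES = ("NBI", "Chl", "Flav")


@dataclass(frozen=True)
class IndexDef:
    """One registry entry: family, required input kind and formula."""

    name: str
    family: str  # asd | multiplex | rgb | dualex
    func: object
    aliases: tuple = ()


def _build_registry() -> dict[str, IndexDef]:
    reg: dict[str, IndexDef] = {}
    alias_rev: dict[str, list] = {}
    for alias, target in ASD_ALIASES.items():
        alias_rev.setdefault(target, []).append(alias)
    for name, fn in _asd_formulas().items():
        reg[name] = IndexDef(name, "asd", fn, tuple(alias_rev.get(name, ())))
    for name, fn in MULTIPLEX_FORMULAS.items():
        reg[name] = IndexDef(name, "multiplex", fn)
    for name, fn in RGB_FORMULAS.items():
        reg[name] = IndexDef(name, "rgb", fn)
    for name in DUALEX_FEATURES:
        reg[name] = IndexDef(name, "dualex", (lambda n: (lambda d: getattr(d, n)))(name))
    return reg


REGISTRY: dict[str, IndexDef] = _build_registry()

FAMILIES = ("asd", "multiplex", "rgb", "dualex")


def family_names(family: str) -> list[str]:
    """Registry index names belonging to one sensor family, in registry order."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return [d.name for d in REGISTRY.values() if d.family == family]


def compute_asd_vis(spectrum: ReflectanceSpectrum, strict: bool = False) -> dict[str, float]:
    """All 28 narrow-band indices for one reflectance spectrum.

    ``strict=True`` evaluates the degenerate printed variant of TBI2 instead
    of its normalized-difference correction.
    """
    if not spectrum.covers(*ASD_RANGE):
        raise ValueError("spectrum must cover 350-2500 nm")
    formulas = _asd_formulas(strict=strict)
    return {name: float(fn(spectrum)) for name, fn in formulas.items()}


def compute_multiplex_vis(reading: FluorescenceReading) -> dict[str, float]:
    """All 9 fluorescence indices for one channel reading."""
    return {name: float(fn(reading)) for name, fn in MULTIPLEX_FORMULAS.items()}


def compute_rgb_vis(stats: RGBPlotStats) -> dict[str, float]:
    """All 14 RGB-camera indices from calibrated band means."""
    if not stats.calibrated:
        stats = stats.calibrate()
    dn = stats.mean_dn
    return {name: float(fn(dn)) for name, fn in RGB_FORMULAS.items()}


def dualex_features(reading: DualexReading) -> dict[str, float]:
    """Leaf-clip sensor outputs used directly as features (validated pass-through)."""
    return {"NBI": float(reading.NBI), "Chl": float(reading.Chl), "Flav": float(reading.Flav)}


# ---------------------------------------------------------------------------
# Feature-table assembly
# ---------------------------------------------------------------------------

TARGETS = ("LNC", "PNC", "NNI")


def build_feature_table(dataset, families=("asd", "multiplex", "rgb", "dualex")) -> pd.DataFrame:
    """Plots × indices feature table with stage labels and N-indicator targets.

    ``dataset`` is a :class:`~wheatn.synthetic.SyntheticDataset`-like object
    exposing per-modality observation tables.  Rows are (plot_id, stage);
    columns are the requested families' index names plus the targets LNC,
    PNC, NNI derived from the plant samples.  Undefined index values stay as
    NaN (count logged); all-NaN columns are dropped with a warning.
    """
    from wheatn.indicators import indicators_table

    if isinstance(families, str):
        families = (families,)
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}")

    ind = indicators_table(dataset.plant_samples).set_index(["plot_id", "stage"])
    if ind.index.has_duplicates:
        raise ValueError("duplicate plot/stage records in plant samples")

    blocks: list[pd.DataFrame] = []
    if "asd" in families:
        rows = {
            key: compute_asd_vis(dataset.spectrum(*key)) for key in dataset.keys()
        }
        blocks.append(pd.DataFrame.from_dict(rows, orient="index"))
    if "multiplex" in families:
        rows = {key: compute_multiplex_vis(dataset.fluorescence_reading(*key)) for key in dataset.keys()}
        blocks.append(pd.DataFrame.from_dict(rows, orient="index"))
    if "rgb" in families:
        rows = {key: compute_rgb_vis(dataset.rgb_stats(*key)) for key in dataset.keys()}
        blocks.append(pd.DataFrame.from_dict(rows, orient="index"))
    if "dualex" in families:
        rows = {key: dualex_features(dataset.dualex_reading(*key)) for key in dataset.keys()}
        blocks.append(pd.DataFrame.from_dict(rows, orient="index"))

    feats = pd.concat(blocks, axis=1)
    feats.index = pd.MultiIndex.from_tuples(feats.index, names=["plot_id", "stage"])
    if feats.index.has_duplicates:
        raise ValueError("duplicate plot/stage feature records")

    n_missing = int(feats.isna().sum().sum())
    if n_missing:
        logger.warning("feature table contains %d missing index value(s)", n_missing)
    all_nan = [c for c in feats.columns if feats[c].isna().all()]
    if all_nan:
        logger.warning("dropping all-missing feature column(s): %s", all_nan)
        feats = feats.drop(columns=all_nan)

    table = feats.join(ind[list(TARGETS)], how="left").reset_index()
    return table
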