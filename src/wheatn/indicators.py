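"""Plant nitrogen indicators: accumulation, concentration, critical N and NNI.

Plot sampling yields organ dry biomass (leaf LB, stem SB, ear EB, in g/m²)
and organ N concentrations (% of dry matter).  From these the module derives

* PNA — plant N accumulation, kg N/ha, summed over organs,
* PNC — whole-plant N concentration, the biomass-weighted mean of the organ
  concentrations (% DM),
* Nc  — the critical N concentration from the winter-wheat dilution curve
  Nc = 4.15 · W^(−0.38) with W the aboveground biomass in Mg DM/ha,
* NNI — the nitrogen nutrition index Nact / Nc, equal to 1 at exactly
  critical N supply, below 1 under deficiency.

Units: biomass is stored in g/m² as sampled and converted internally
(1 g/m² = 10 kg/ha); percentages are divided by 100 inside products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Winter-wheat critical N dilution curve coefficients (Nc in % DM, W in Mg/ha)
NC_COEF = 4.15
NC_EXP = -0.38

G_M2_TO_KG_HA = 10.0
KG_HA_TO_MG_HA = 1e-3


@dataclass(frozen=True)
class OrganSample:
    """Organ-level dry biomass and N concentration for one plot/stage.

    Biomass in g/m² (LB leaf, SB stem, EB ear); concentrations in % DM.
    Pre-heading samples have ``EB = 0``.
    """

    LB: float
    SB: float
    EB: float
    LNC: float
    SNC: float
    ENC: float

    def __post_init__(self) -> None:
        for name in ("LB", "SB", "EB"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative biomass {name}")
        for name in ("LNC", "SNC", "ENC"):
            c = getattr(self, name)
            if not 0.0 <= c <= 10.0:
                raise ValueError(f"concentration {name}={c} outside [0, 10] %")
        if self.LB + self.SB + self.EB <= 0:
            raise ValueError("total biomass must be positive")

    @property
    def total_biomass(self) -> float:
        """Total aboveground biomass, g/m²."""
        return self.LB + self.SB + self.EB

    @property
    def biomass_mg_ha(self) -> float:
        """Total aboveground biomass, Mg DM/ha."""
        return self.total_biomass * G_M2_TO_KG_HA * KG_HA_TO_MG_HA


@dataclass(frozen=True)
class NIndicators:
    """Derived nitrogen indicators for one plot/stage."""

    PNA: float  # kg N/ha
    PNC: float  # % DM
    Nc: float  # % DM
    NNI: float  # dimensionless
    stage: str = ""


def plant_n_accumulation(sample: OrganSample) -> float:
    """Plant N accumulation PNA (kg N/ha) summed over leaf, stem and ear.

    Each organ contributes biomass (converted g/m² → kg/ha) times its N
    concentration (% → fraction).
    """
    return sum(
        b * G_M2_TO_KG_HA * c / 100.0
        for b, c in ((sample.LB, sample.LNC), (sample.SB, sample.SNC), (sample.EB, sample.ENC))
    )


def plant_n_concentration(sample: OrganSample) -> float:
    """Whole-plant N concentration PNC (% DM).

    PNA divided by total biomass (both kg/ha), expressed as a percentage;
    algebraically the biomass-weighted mean of the organ concentrations.
    """
    total_kg_ha = sample.total_biomass * G_M2_TO_KG_HA
    return plant_n_accumulation(sample) / total_kg_ha * 100.0


def critical_n(W):
    """Critical N concentration Nc (% DM) at aboveground biomass W (Mg DM/ha).

    Winter-wheat dilution curve ``Nc = 4.15 · W**(-0.38)``: the minimum plant
    N concentration allowing maximal growth declines as the crop accumulates
    biomass.  Strictly decreasing in W.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("biomass W must be positive")
    out = NC_COEF * W**NC_EXP
    return float(out) if out.ndim == 0 else out


def nni(Nact, W):
    """Nitrogen nutrition index NNI = Nact / Nc(W).

    ``Nact`` is the measured plant N concentration (% DM); NNI = 1 at exactly
    critical supply, < 1 deficient, > 1 luxury consumption.
    """
    Nact = np.asarray(Nact, dtype=float)
    if np.any(Nact < 0):
        raise ValueError("Nact must be non-negative")
    out = Nact / critical_n(W)
    return float(out) if out.ndim == 0 else out


def indicators(sample: OrganSample, stage: str = "") -> NIndicators:
    """All four indicators for one sample; Nact is taken as PNC."""
    pna = plant_n_accumulation(sample)
    pnc = plant_n_concentration(sample)
    nc = critical_n(sample.biomass_mg_ha)
    return NIndicators(PNA=pna, PNC=pnc, Nc=nc, NNI=pnc / nc, stage=stage)


def indicators_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Derive the indicator table from a plant-sampling table.

    Parameters
    ----------
    samples
        Columns ``plot_id, stage, LB, SB, EB, LNC, SNC, ENC`` (biomass g/m²,
        concentrations % DM), one row per plot/stage.

    Returns
    -------
    DataFrame with columns ``plot_id, stage, PNA, PNC, Nc, NNI`` (and LNC
    carried through as the leaf-level indicator).
    """
    required = {"plot_id", "stage", "LB", "SB", "EB", "LNC", "SNC", "ENC"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"plant-sampling table missing columns {sorted(missing)}")
    rows = []
    for rec in samples.itertuples(index=False):
        s = OrganSample(LB=rec.LB, SB=rec.SB, EB=rec.EB, LNC=rec.LNC, SNC=rec.SNC, ENC=rec.ENC)
        ind = indicators(s, stage=rec.stage)
        rows.append(
            {
                "plot_id": rec.plot_id,
                "stage": rec.stage,
                "PNA": ind.PNA,
                "PNC": ind.PNC,
                "Nc": ind.Nc,
                "NNI": ind.NNI,
                "LNC": rec.LNC,
            }
        )
    return pd.DataFrame(rows)
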