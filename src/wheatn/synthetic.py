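"""Seeded multi-sensor synthetic datasets for a graded-N wheat experiment.

The generator emulates a two-stage (Feekes 5 stem elongation, Feekes 11 grain
filling) plot experiment with applied N spanning 0–225 kg/ha.  Each plot and
stage gets a latent agronomic state — aboveground biomass ``W`` (Mg DM/ha),
actual plant N concentration ``Nact`` (% DM), canopy chlorophyll and flavonol
proxies, and a soil-visible fraction — from which one observation per sensor
modality is synthesised:

* a 350–2500 nm reflectance spectrum as a linear soil/vegetation mixture whose
  red absorption deepens and whose red edge shifts to longer wavelengths with
  chlorophyll;
* six fluorescence channel signals whose UV-excited channels are screened by
  flavonols and whose far-red/red ratios rise with chlorophyll;
* leaf-clip readings (Chl, Flav, and their ratio NBI);
* RGB band digital numbers (band-window means of the spectrum mapped onto a
  0–255 DN scale with white/black panel DNs) so empirical-line calibration is
  exercisable end to end;
* an organ-level plant sample (leaf/stem/ear biomass and N concentrations)
  whose derived PNC and NNI reproduce the latent state.

The generative chain is monotone by construction: applied N raises biomass
and the N nutrition level through a saturating link, Nact follows the
critical-N dilution curve scaled by the target NNI, and chlorophyll
(flavonols) increase (decrease) with leaf N.  Fixed seed ⇒ bitwise-identical
output; setting every noise SD to zero makes plots with equal N rates
identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from wheatn.indicators import critical_n
from wheatn.indices import DualexReading, FluorescenceReading
from wheatn.spectra import ReflectanceSpectrum, RGBPlotStats

WAVELENGTHS = np.arange(350, 2501)

STAGES = ("Feekes5", "Feekes11")

# Per-stage generative constants.  w0/w1: biomass intercept/slope (Mg DM/ha)
# against the saturating N-response; nni0/nni1: same for the target NNI;
# soil0/soil1: soil-visible fraction; leaf/stem/ear biomass fractions and the
# organ-concentration ratios k_leaf = LNC/PNC, k_ear = ENC/PNC (k_stem follows
# from the weighted mean being PNC).
STAGE_PARAMS: dict[str, dict[str, float]] = {
    "Feekes5": dict(
        w0=0.70, w1=0.90, nni0=0.70, nni1=0.70, soil0=0.55, soil1=-0.35,
        leaf_frac=0.55, stem_frac=0.45, ear_frac=0.0, k_leaf=1.15, k_ear=0.0,
    ),
    "Feekes11": dict(
        w0=6.0, w1=4.0, nni0=0.58, nni1=0.48, soil0=0.18, soil1=-0.10,
        leaf_frac=0.18, stem_frac=0.50, ear_frac=0.32, k_leaf=1.75, k_ear=1.0,
    ),
}

N_RATE_MAX = 225.0

# RGB synthesis: band windows (nm), panel DNs and the reflectance mapped to
# the white panel
RGB_WINDOWS = {"B": (400, 500), "G": (500, 600), "R": (600, 700)}
PANEL_WHITE_DN = 242.0
PANEL_BLACK_DN = 6.0
WHITE_REFLECTANCE = 0.6


def _saturating(f: np.ndarray) -> np.ndarray:
    """Michaelis-type N response on the normalized rate f = n_rate / 225."""
    return 1.6 * f / (f + 0.6)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one synthetic graded-N experiment."""

    n_plots: int = 104
    stages: tuple[str, ...] = STAGES
    n_rates: tuple[float, ...] | None = None  # kg N/ha per plot; default 0-225 gradient
    noise_sd_spectral: float = 0.01  # relative reflectance noise per band
    noise_sd_channel: float = 0.03  # relative fluorescence / leaf-clip noise
    noise_sd_latent: float = 0.10  # plot-to-plot agronomic variability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 4:
            raise ValueError("n_plots must be at least 4")
        for name in ("noise_sd_spectral", "noise_sd_channel", "noise_sd_latent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for s in self.stages:
            if s not in STAGE_PARAMS:
                raise ValueError(f"unknown stage label {s!r}; known: {list(STAGE_PARAMS)}")
        if self.n_rates is not None:
            object.__setattr__(self, "n_rates", tuple(float(r) for r in self.n_rates))
            if len(self.n_rates) != self.n_plots:
                raise ValueError("n_rates must have one entry per plot")
            if min(self.n_rates) < 0 or max(self.n_rates) > 300:
                raise ValueError("n_rates must lie within [0, 300] kg/ha")

    def rates(self) -> np.ndarray:
        if self.n_rates is not None:
            return np.asarray(self.n_rates, dtype=float)
        return np.linspace(0.0, N_RATE_MAX, self.n_plots)


@dataclass(frozen=True)
class LatentPlotState:
    """Latent agronomic state of one plot at one stage."""

    W: float  # aboveground biomass, Mg DM/ha
    Nact: float  # actual plant N concentration, % DM
    chl: float  # canopy chlorophyll proxy, arbitrary units > 0
    flav: float  # flavonol proxy, arbitrary units > 0
    soil_fraction: float  # visible soil fraction in [0, 1]

    def __post_init__(self) -> None:
        if not self.W > 0:
            raise ValueError("biomass W must be positive")
        if not self.Nact > 0:
            raise ValueError("Nact must be positive")
        if not (self.chl > 0 and self.flav > 0):
            raise ValueError("chl and flav proxies must be positive")
        if not 0.0 <= self.soil_fraction <= 1.0:
            raise ValueError("soil_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Fixed endmember spectra (documented closed-form piecewise-smooth curves)
# ---------------------------------------------------------------------------


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def soil_endmember(wavelengths: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Bright dry-soil reflectance: rising toward SWIR with water absorptions."""
    wl = np.asarray(wavelengths, dtype=float)
    base = 0.10 + 0.22 * (1.0 - np.exp(-(wl - 350.0) / 900.0))
    dips = (1.0 - 0.25 * _gauss(wl, 1450, 45)) * (1.0 - 0.35 * _gauss(wl, 1940, 60))
    return np.clip(base * dips, 0.0, 1.0)


def vegetation_endmember(chl: float, wavelengths: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Green-vegetation reflectance parameterized by the chlorophyll proxy.

    Red absorption around 670 nm deepens with chl; the red-edge logistic
    midpoint shifts to longer wavelengths with chl; the NIR plateau carries
    leaf-water absorption features and a gentle SWIR decline.
    """
    wl = np.asarray(wavelengths, dtype=float)
    d = chl / (chl + 25.0)  # pigment absorption depth in (0, 1)
    r670 = 0.02 + 0.22 * (1.0 - d)
    lam_mid = 692.0 + 30.0 * d
    logistic = 1.0 / (1.0 + np.exp(-(wl - lam_mid) / 11.0))

    g_amp = 0.04 + 0.13 * (1.0 - d)
    visible = 0.03 + g_amp * _gauss(wl, 550, 38) + (r670 - 0.03) * _gauss(wl, 668, 40)

    nir = 0.48 * (
        1.0
        - 0.05 * _gauss(wl, 970, 25)
        - 0.10 * _gauss(wl, 1200, 35)
        - 0.50 * _gauss(wl, 1450, 60)
        - 0.65 * _gauss(wl, 1940, 80)
        - 0.18 * np.clip((wl - 1300.0) / 1200.0, 0.0, 1.0)
    )
    return np.clip(visible * (1.0 - logistic) + nir * logistic, 0.0, 1.0)


def latent_to_reflectance(
    state: LatentPlotState, wavelengths: np.ndarray = WAVELENGTHS
) -> ReflectanceSpectrum:
    """Noise-free canopy reflectance: linear soil/vegetation mixture."""
    veg = vegetation_endmember(state.chl, wavelengths)
    soil = soil_endmember(wavelengths)
    mix = state.soil_fraction * soil + (1.0 - state.soil_fraction) * veg
    return ReflectanceSpectrum(wavelengths=wavelengths, values=np.clip(mix, 0.0, 1.0))


def latent_to_fluorescence(state: LatentPlotState) -> FluorescenceReading:
    """Noise-free fluorescence channels for one latent state.

    UV-excited fluorescence is attenuated exponentially by the flavonol layer
    (UV screening), so FRF_UV falls with flav; far-red emission rises with
    chlorophyll through a saturating link, so the simple fluorescence ratios
    SFR_G/SFR_R rise with chl and the red/UV excitation ratio FER_RUV rises
    without bound as flav grows.
    """
    s = state.chl / (state.chl + 15.0)
    screen = np.exp(-0.9 * state.flav)
    return FluorescenceReading(
        BGF_UV=0.35 * np.exp(-0.25 * state.flav),
        FRF_UV=2.0 * s * screen,
        FRF_G=1.6 * s,
        RF_G=0.8 * (1.0 - 0.5 * s),
        FRF_R=2.0 * s,
        RF_R=0.9 * (1.0 - 0.5 * s),
    )


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """All generated tables for one experiment run, keyed by (plot_id, stage)."""

    config: ExperimentConfig
    latent: pd.DataFrame
    spectra_values: np.ndarray  # rows aligned with `latent`
    wavelengths: np.ndarray
    fluorescence: pd.DataFrame
    dualex: pd.DataFrame
    rgb: pd.DataFrame
    plant_samples: pd.DataFrame

    def __post_init__(self) -> None:
        self._row = {
            (r.plot_id, r.stage): i for i, r in enumerate(self.latent.itertuples(index=False))
        }

    def keys(self) -> list[tuple]:
        return list(self._row)

    def spectrum(self, plot_id, stage) -> ReflectanceSpectrum:
        return ReflectanceSpectrum(
            wavelengths=self.wavelengths, values=self.spectra_values[self._row[(plot_id, stage)]]
        )

    def fluorescence_reading(self, plot_id, stage) -> FluorescenceReading:
        r = self.fluorescence.iloc[self._row[(plot_id, stage)]]
        return FluorescenceReading(
            BGF_UV=r.BGF_UV, FRF_UV=r.FRF_UV, FRF_G=r.FRF_G, RF_G=r.RF_G, FRF_R=r.FRF_R, RF_R=r.RF_R
        )

    def dualex_reading(self, plot_id, stage) -> DualexReading:
        r = self.dualex.iloc[self._row[(plot_id, stage)]]
        return DualexReading(NBI=r.NBI, Chl=r.Chl, Flav=r.Flav)

    def rgb_stats(self, plot_id, stage) -> RGBPlotStats:
        r = self.rgb.iloc[self._row[(plot_id, stage)]]
        return RGBPlotStats(
            mean_dn={b: getattr(r, f"mean_DN_{b}") for b in ("R", "G", "B")},
            white_dn={b: getattr(r, f"white_DN_{b}") for b in ("R", "G", "B")},
            black_dn={b: getattr(r, f"black_DN_{b}") for b in ("R", "G", "B")},
            stage=stage,
            plot_id=plot_id,
        )

    def latent_state(self, plot_id, stage) -> LatentPlotState:
        r = self.latent.iloc[self._row[(plot_id, stage)]]
        return LatentPlotState(
            W=r.W, Nact=r.Nact, chl=r.chl, flav=r.flav, soil_fraction=r.soil_fraction
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _chl_from_lnc(lnc: np.ndarray) -> np.ndarray:
    """Saturating (Michaelis-type) chlorophyll–leaf-N link."""
    return 80.0 * lnc / (lnc + 2.5)


def _flav_from_lnc(lnc: np.ndarray) -> np.ndarray:
    """Flavonol accumulation declines with leaf N (dilution of UV screens)."""
    return 0.35 + 1.8 * np.exp(-0.45 * lnc)


def generate_experiment(config: ExperimentConfig | None = None) -> SyntheticDataset:
    """Generate the full multi-sensor dataset for one experiment.

    Deterministic for a fixed ``config.seed``; one observation per sensor
    modality per plot/stage, plus an organ-level plant sample whose derived
    PNC and NNI reproduce the latent state.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(config.seed)
    rates = config.rates()
    n = config.n_plots
    f = rates / N_RATE_MAX
    sat = _saturating(f)

    latent_rows = []
    spectra = []
    fluo_rows = []
    dualex_rows = []
    rgb_rows = []
    sample_rows = []

    soil_prev: dict[int, float] = {}

    for stage in config.stages:
        p = STAGE_PARAMS[stage]
        w_noise = np.exp(rng.normal(0.0, config.noise_sd_latent, n))
        nni_noise = rng.normal(0.0, 0.6 * config.noise_sd_latent, n)
        soil_noise = rng.normal(0.0, 0.5 * config.noise_sd_latent, n)

        W = (p["w0"] + p["w1"] * sat) * w_noise
        nni_target = np.clip(p["nni0"] + p["nni1"] * sat + nni_noise, 0.2, 2.0)
        Nc = critical_n(W)
        pnc = nni_target * Nc  # Nact == PNC by construction
        lnc = np.clip(p["k_leaf"] * pnc, 0.05, 9.9)
        chl = _chl_from_lnc(lnc)
        flav = _flav_from_lnc(lnc)
        soil_frac = np.clip(p["soil0"] + p["soil1"] * sat + soil_noise, 0.02, 0.95)

        # later-stage canopy always covers more soil than the earlier one
        for i in range(n):
            if i in soil_prev:
                soil_frac[i] = min(soil_frac[i], 0.9 * soil_prev[i])
            else:
                soil_prev[i] = soil_frac[i]

        spec_noise = rng.normal(0.0, config.noise_sd_spectral, (n, WAVELENGTHS.size))
        chan_noise = rng.normal(0.0, config.noise_sd_channel, (n, 6))
        leaf_noise = rng.normal(0.0, config.noise_sd_channel, (n, 2))

        k_stem = (1.0 - p["leaf_frac"] * p["k_leaf"] - p["ear_frac"] * p["k_ear"]) / p["stem_frac"]

        for i in range(n):
            state = LatentPlotState(
                W=float(W[i]),
                Nact=float(pnc[i]),
                chl=float(chl[i]),
                flav=float(flav[i]),
                soil_fraction=float(soil_frac[i]),
            )
            latent_rows.append(
                {
                    "plot_id": i,
                    "stage": stage,
                    "n_rate": float(rates[i]),
                    "W": state.W,
                    "Nact": state.Nact,
                    "chl": state.chl,
                    "flav": state.flav,
                    "soil_fraction": state.soil_fraction,
                    "Nc": float(Nc[i]),
                    "NNI": float(pnc[i] / Nc[i]),
                    "PNC": float(pnc[i]),
                    "LNC": float(lnc[i]),
                }
            )

            spec = latent_to_reflectance(state).values * (1.0 + spec_noise[i])
            spec = np.clip(spec, 0.0, 1.0)
            spectra.append(spec)

            fl = latent_to_fluorescence(state)
            chans = np.array([fl.BGF_UV, fl.FRF_UV, fl.FRF_G, fl.RF_G, fl.FRF_R, fl.RF_R])
            chans = chans * np.exp(chan_noise[i])
            fluo_rows.append(
                dict(
                    plot_id=i, stage=stage,
                    BGF_UV=chans[0], FRF_UV=chans[1], FRF_G=chans[2],
                    RF_G=chans[3], FRF_R=chans[4], RF_R=chans[5],
                )
            )

            chl_dx = 1.1 * state.chl * np.exp(leaf_noise[i, 0])
            flav_dx = state.flav * np.exp(leaf_noise[i, 1])
            dualex_rows.append(
                dict(plot_id=i, stage=stage, NBI=chl_dx / flav_dx, Chl=chl_dx, Flav=flav_dx)
            )

            dn = {}
            for bname, (lo, hi) in RGB_WINDOWS.items():
                sel = (WAVELENGTHS >= lo) & (WAVELENGTHS < hi)
                refl = float(spec[sel].mean())
                dn[bname] = PANEL_BLACK_DN + (PANEL_WHITE_DN - PANEL_BLACK_DN) * min(
                    refl / WHITE_REFLECTANCE, 1.0
                )
            rgb_rows.append(
                dict(
                    plot_id=i, stage=stage,
                    mean_DN_R=dn["R"], mean_DN_G=dn["G"], mean_DN_B=dn["B"],
                    white_DN_R=PANEL_WHITE_DN, white_DN_G=PANEL_WHITE_DN, white_DN_B=PANEL_WHITE_DN,
                    black_DN_R=PANEL_BLACK_DN, black_DN_G=PANEL_BLACK_DN, black_DN_B=PANEL_BLACK_DN,
                )
            )

            total_g_m2 = state.W * 100.0  # Mg/ha -> g/m²
            sample_rows.append(
                dict(
                    plot_id=i, stage=stage,
                    LB=p["leaf_frac"] * total_g_m2,
                    SB=p["stem_frac"] * total_g_m2,
                    EB=p["ear_frac"] * total_g_m2,
                    LNC=float(lnc[i]),
                    SNC=float(np.clip(k_stem * pnc[i], 0.0, 9.9)),
                    ENC=float(np.clip(p["k_ear"] * pnc[i], 0.0, 9.9)),
                )
            )

    return SyntheticDataset(
        config=config,
        latent=pd.DataFrame(latent_rows),
        spectra_values=np.asarray(spectra),
        wavelengths=WAVELENGTHS.copy(),
        fluorescence=pd.DataFrame(fluo_rows),
        dualex=pd.DataFrame(dualex_rows),
        rgb=pd.DataFrame(rgb_rows),
        plant_samples=pd.DataFrame(sample_rows),
    )


# ---------------------------------------------------------------------------
# Disk round-trip
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write one directory per run: per-modality CSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long = []
    for (plot_id, stage), i in dataset._row.items():
        long.append(
            pd.DataFrame(
                {
                    "plot_id": plot_id,
                    "stage": stage,
                    "wavelength_nm": dataset.wavelengths,
                    "reflectance": dataset.spectra_values[i],
                }
            )
        )
    pd.concat(long, ignore_index=True).to_csv(out / "spectra.csv", index=False)
    dataset.fluorescence.to_csv(out / "fluorescence.csv", index=False)
    dataset.dualex.to_csv(out / "dualex.csv", index=False)
    dataset.rgb.to_csv(out / "rgb.csv", index=False)
    dataset.plant_samples.to_csv(out / "plant_samples.csv", index=False)
    dataset.latent.to_csv(out / "latent.csv", index=False)
    manifest = dataclasses.asdict(dataset.config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return out


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Reload a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("stages") is not None:
        manifest["stages"] = tuple(manifest["stages"])
    if manifest.get("n_rates") is not None:
        manifest["n_rates"] = tuple(manifest["n_rates"])
    config = ExperimentConfig(**manifest)
    latent = pd.read_csv(d / "latent.csv")
    spectra_long = pd.read_csv(d / "spectra.csv")
    wl = np.sort(spectra_long["wavelength_nm"].unique())
    values = []
    grouped = spectra_long.set_index(["plot_id", "stage"]).sort_index()
    for r in latent.itertuples(index=False):
        sub = grouped.loc[(r.plot_id, r.stage)].sort_values("wavelength_nm")
        values.append(sub["reflectance"].to_numpy())
    return SyntheticDataset(
        config=config,
        latent=latent,
        spectra_values=np.asarray(values),
        wavelengths=wl,
        fluorescence=pd.read_csv(d / "fluorescence.csv"),
        dualex=pd.read_csv(d / "dualex.csv"),
        rgb=pd.read_csv(d / "rgb.csv"),
        plant_samples=pd.read_csv(d / "plant_samples.csv"),
    )
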