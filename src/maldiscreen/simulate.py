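"""Synthetic data with the statistical structure the analyses assume.

This module generates every dataset the pipeline consumes: whole-cell
linear-mode MALDI-TOF spectra with condition-dependent biomarker peaks,
96-compound screening plates with staggered per-set controls, thermal-shift
(melt curve) tables, and isothermal dose-response series.  Everything is a
pure function of (config, seed).

The spectral model
------------------
A spectrum on a uniform m/z grid over 2000-20000 Da is the sum of

* a panel of phenotype biomarker peaks (defaults at m/z 4632, 4964, 6891)
  whose areas are multiplied by condition-specific factors: TLR stimulation
  (e.g. LPS) lowers the resting marker 4632, raises the stimulated marker
  4964 and lowers 6891;
* a fixed background fingerprint of Gaussian peaks (positions drawn once per
  config, shared by every spectrum);
* a smooth exponentially decaying chemical baseline; and
* noise: a whole-spectrum intensity scale factor (log-normal, large CV -- it
  cancels in intraspectra ratios), small independent per-peak area factors
  (log-normal), additive Gaussian grid noise, and a small m/z jitter.

Peak widths follow the linear-mode resolution model sigma = mz / 2000 Da
(about 850 FWHM resolving power).

Inhibitors attenuate the stimulated condition toward the resting phenotype:
an inhibition fraction f rescales every condition multiplier m to
``1 + (m - 1) * (1 - f)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io import Spectrum
from .thermal import melt_model, params_for_tm, DEFAULT_TEMPERATURES

__all__ = [
    "PeakSpec",
    "SpectrumSimConfig",
    "ScreenSimConfig",
    "DoseSeriesSimConfig",
    "ProteinMeltSpec",
    "TPPSimConfig",
    "default_panel",
    "generate_spectrum",
    "simulate_screen",
    "simulate_dose_series",
    "simulate_tpp",
    "simulate_itdr",
    "expected_ratio",
    "config_to_yaml",
    "config_from_yaml",
]

STIMULI = ("LPS", "Pam2CSK4", "Pam3CSK4", "IFN-gamma")


@dataclass
class PeakSpec:
    """One simulated peak: rest area, width, and per-condition area factors."""

    mz_center: float
    rest_intensity: float
    width_sigma: float | None = None  # defaults to mz / 2000
    condition_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 2000.0 <= self.mz_center <= 20000.0:
            raise ConfigError(f"peak m/z {self.mz_center} outside [2000, 20000]")
        if self.rest_intensity <= 0:
            raise ConfigError("rest_intensity must be > 0")
        if self.width_sigma is None:
            self.width_sigma = self.mz_center / 2000.0
        if self.width_sigma <= 0 or self.width_sigma >= 0.05 * self.mz_center:
            raise ConfigError("width_sigma must be in (0, 0.05 x mz_center)")
        if any(m <= 0 for m in self.condition_multipliers.values()):
            raise ConfigError("condition multipliers must be > 0")

    def multiplier(self, condition: str, inhibition: float = 0.0) -> float:
        m = self.condition_multipliers.get(condition, 1.0)
        return 1.0 + (m - 1.0) * (1.0 - inhibition)


def default_panel() -> list[PeakSpec]:
    """The three phenotype biomarker peaks with stimulation multipliers.

    Multipliers reproduce the direction of the stimulation response (4632
    down, 4964 up, 6891 down) with magnitudes giving a ~3-fold stimulated /
    resting ratio shift for LPS; 6891 is the more variable marker, quantified
    but excluded from the decision statistic downstream.
    """
    return [
        PeakSpec(4632.0, 200.0, None, {
            "LPS": 0.6, "Pam2CSK4": 0.65, "Pam3CSK4": 0.7, "IFN-gamma": 0.85,
            "apoptotic": 0.75,
        }),
        PeakSpec(4964.0, 150.0, None, {
            "LPS": 1.8, "Pam2CSK4": 1.7, "Pam3CSK4": 1.55, "IFN-gamma": 1.2,
            "apoptotic": 0.8,
        }),
        PeakSpec(6891.0, 100.0, None, {
            "LPS": 0.5, "Pam2CSK4": 0.55, "Pam3CSK4": 0.6, "IFN-gamma": 0.9,
            "apoptotic": 1.6,
        }),
    ]


@dataclass
class SpectrumSimConfig:
    """Generative description of a single-condition spectrum population."""

    peak_panel: list = field(default_factory=default_panel)
    n_background_peaks: int = 30
    baseline_amplitude: float = 200.0
    baseline_decay: float = 1500.0
    multiplicative_cv: float = 0.015     # independent per-peak area CV
    global_intensity_cv: float = 0.25    # shared whole-spectrum scale CV
    additive_noise_sd: float = 0.3
    mz_jitter_sd: float = 0.3
    grid_spacing: float = 1.0
    mass_range: tuple = (2000.0, 20000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ConfigError("grid_spacing must be > 0")
        if not 0 <= self.multiplicative_cv < 1:
            raise ConfigError("multiplicative_cv must be in [0, 1)")
        low, high = self.mass_range
        if not low < high:
            raise ConfigError("mass_range low must be < high")
        if self.baseline_decay <= 0:
            raise ConfigError("baseline_decay must be > 0")

    @property
    def conditions(self) -> set:
        labels = {"resting"}
        for pk in self.peak_panel:
            labels.update(pk.condition_multipliers)
        return labels

    def grid(self) -> np.ndarray:
        low, high = self.mass_range
        return np.arange(low, high + self.grid_spacing / 2, self.grid_spacing)

    def background_peaks(self) -> list[PeakSpec]:
        """Fixed background fingerprint, drawn once from the config seed."""
        cached = getattr(self, "_bg_cache", None)
        if cached is not None:
            return cached
        rng = np.random.default_rng([int(self.seed), 0x0B6])
        low, high = self.mass_range
        centers = rng.uniform(low + 200, min(high, 18000.0), self.n_background_peaks)
        areas = 40.0 * rng.lognormal(0.0, 0.6, self.n_background_peaks)
        peaks = [PeakSpec(c, a) for c, a in zip(np.sort(centers), areas)]
        object.__setattr__(self, "_bg_cache", peaks)
        return peaks


def _lognormal_factor(rng, cv: float, size=None):
    """Log-normal multiplicative factor with expectation exactly 1."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * s * s, s, size)


def _add_gaussian(grid, inten, center, sigma, area, spacing):
    lo = np.searchsorted(grid, center - 6 * sigma)
    hi = np.searchsorted(grid, center + 6 * sigma)
    if hi <= lo:
        return
    x = grid[lo:hi]
    inten[lo:hi] += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2
    )


def generate_spectrum(
    config: SpectrumSimConfig,
    condition: str = "resting",
    seed: int | None = None,
    inhibition: float = 0.0,
    metadata: dict | None = None,
) -> Spectrum:
    """Draw one spectrum for the given condition.

    ``inhibition`` in [0, 1] pulls the condition's multipliers back toward
    the resting phenotype (1 = fully resting).  Deterministic for a fixed
    (config, condition, seed, inhibition).
    """
    if condition not in config.conditions:
        raise ConfigError(
            f"unknown condition {condition!r}; known: {sorted(config.conditions)}"
        )
    if not 0.0 <= inhibition <= 1.0:
        raise ConfigError("inhibition must be in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = config.grid()
    inten = np.zeros_like(grid)
    scale = float(_lognormal_factor(rng, config.global_intensity_cv))

    for pk in list(config.peak_panel) + config.background_peaks():
        mult = pk.multiplier(condition, inhibition)
        area = pk.rest_intensity * mult * float(_lognormal_factor(rng, config.multiplicative_cv))
        center = pk.mz_center + rng.normal(0.0, config.mz_jitter_sd)
        _add_gaussian(grid, inten, center, pk.width_sigma, area * scale, config.grid_spacing)

    if config.baseline_amplitude:
        inten += scale * config.baseline_amplitude * np.exp(-grid / config.baseline_decay)
    if config.additive_noise_sd:
        inten += rng.normal(0.0, config.additive_noise_sd, inten.shape)
        np.clip(inten, 0.0, None, out=inten)

    md = {"condition": condition, "inhibition": inhibition, "seed": seed}
    if metadata:
        md.update(metadata)
    return Spectrum(grid, inten, md)


def inhibition_for_effect(
    config: SpectrumSimConfig, condition: str, effect_fraction: float
) -> float:
    """Inhibition fraction whose expected percent effect equals the target.

    The measured percent effect lives on the (normalized) 4964/4632 ratio
    scale, which is a nonlinear function of the inhibition fraction; dose
    series parameterized by a measured-scale IC50 must therefore invert
    that map.  Closed form from the ratio algebra; result clipped to [0, 1].
    """
    panel = {pk.mz_center: pk for pk in config.peak_panel}
    num, den = panel[4964.0], panel[4632.0]
    r0 = expected_ratio(config, condition, 0.0)
    r1 = expected_ratio(config, condition, 1.0)
    target = r0 - effect_fraction * (r0 - r1)
    n0 = num.rest_intensity * 1.0
    d0 = den.rest_intensity * 1.0
    mn = num.condition_multipliers.get(condition, 1.0)
    md = den.condition_multipliers.get(condition, 1.0)
    denom = n0 * (mn - 1.0) - target * d0 * (md - 1.0)
    if denom == 0:
        return 0.0
    u = (target * d0 - n0) / denom  # u = 1 - inhibition
    return float(np.clip(1.0 - u, 0.0, 1.0))


def expected_ratio(config: SpectrumSimConfig, condition: str, inhibition: float = 0.0) -> float:
    """Noise-free expectation of the 4964/4632 area ratio under a condition."""
    panel = {pk.mz_center: pk for pk in config.peak_panel}
    num = panel[4964.0]
    den = panel[4632.0]
    return (
        num.rest_intensity * num.multiplier(condition, inhibition)
        / (den.rest_intensity * den.multiplier(condition, inhibition))
    )


# ---------------------------------------------------------------------------
# screening plates
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """A blind screen: compounds staggered into sets with per-set controls.

    Defaults mirror the assay design: 96 compounds in 8 sets, each set with
    its own full-inhibitor positive control (NG-25-like) and non-inhibiting
    negative control (MRT68601-like), technical triplicate spectra, three
    biological replicate plates, 5 uM test concentration, and two true
    actives.
    """

    n_compounds: int = 96
    n_sets: int = 8
    technical_replicates: int = 3
    biological_replicates: int = 3
    active_compounds: dict = field(
        default_factory=lambda: {"C017": 1.0, "C059": 0.92}
    )
    stimulus: str = "LPS"
    concentration: float = 5e-6  # molar
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0 or self.n_sets <= 0:
            raise ConfigError("n_compounds and n_sets must be positive")
        if self.n_compounds % self.n_sets:
            raise ConfigError("n_compounds must be divisible by n_sets")
        for cid, frac in self.active_compounds.items():
            if cid not in self.compound_ids():
                raise ConfigError(f"active compound {cid!r} not in the compound list")
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("inhibition fractions must be in [0, 1]")

    def compound_ids(self) -> list[str]:
        return [f"C{i + 1:03d}" for i in range(self.n_compounds)]


def simulate_screen(
    config: ScreenSimConfig,
    spectrum_config: SpectrumSimConfig | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate every spectrum of a blind screen plus its plate map.

    One spectrum per well per technical replicate; every well is annotated in
    the returned plate-map DataFrame (same schema as
    :func:`maldiscreen.io.read_plate_map`).
    """
    scfg = spectrum_config or SpectrumSimConfig(seed=config.seed)
    per_set = config.n_compounds // config.n_sets
    compounds = config.compound_ids()
    spectra: list[Spectrum] = []
    rows = []
    counter = 0
    for bio in range(1, config.biological_replicates + 1):
        plate = f"BR{bio}"
        for s in range(config.n_sets):
            set_id = f"S{s + 1}"
            members = [
                (compounds[s * per_set + j], "test",
                 config.active_compounds.get(compounds[s * per_set + j], 0.0))
                for j in range(per_set)
            ]
            members.append((None, "positive_control", 1.0))
            members.append((None, "negative_control", 0.0))
            for k, (compound, role, inhibition) in enumerate(members):
                well = (
                    f"{set_id}-{compound}" if compound
                    else f"{set_id}-{'POS' if role == 'positive_control' else 'NEG'}"
                )
                for tech in range(1, config.technical_replicates + 1):
                    counter += 1
                    seed = np.random.SeedSequence(
                        [int(config.seed), bio, s, k, tech]
                    ).generate_state(1)[0]
                    md = {
                        "plate": plate,
                        "well": well,
                        "role": role,
                        "compound": compound,
                        "set": set_id,
                        "technical_replicate": tech,
                        "biological_replicate": bio,
                    }
                    spectra.append(
                        generate_spectrum(
                            scfg, config.stimulus, int(seed), inhibition, md
                        )
                    )
                    rows.append(
                        {
                            "plate": plate,
                            "well": well,
                            "role": role,
                            "compound": compound,
                            "concentration": config.concentration if role == "test" else None,
                            "set": set_id,
                            "technical_replicate": tech,
                            "biological_replicate": bio,
                        }
                    )
    return spectra, pd.DataFrame(rows)


@dataclass
class DoseSeriesSimConfig:
    """Concentration series of one inhibitor measured by the MALDI assay.

    Occupancy follows a logistic in concentration with the given ic50 and
    Hill slope; each concentration well gets technical-replicate spectra plus
    per-plate stimulated/inhibited controls for percent-effect anchoring.
    Concentrations in uM (default spans 10 nM - 10 uM around the reference
    inhibitor's potency).
    """

    concentrations: tuple = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
    ic50: float = 0.45          # uM
    hill: float = 1.0
    max_inhibition: float = 1.0
    technical_replicates: int = 3
    biological_replicates: int = 3
    stimulus: str = "LPS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ConfigError("ic50 must be > 0")
        if any(c < 0 for c in self.concentrations):
            raise ConfigError("concentrations must be >= 0")


def simulate_dose_series(
    config: DoseSeriesSimConfig,
    spectrum_config: SpectrumSimConfig | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Spectra + plate map for an inhibitor concentration series."""
    scfg = spectrum_config or SpectrumSimConfig(seed=config.seed)
    spectra: list[Spectrum] = []
    rows = []
    for bio in range(1, config.biological_replicates + 1):
        plate = f"BR{bio}"
        wells = [
            (None, "positive_control", 1.0, None),
            (None, "negative_control", 0.0, None),
            (None, "positive_control", 1.0, None),
            (None, "negative_control", 0.0, None),
        ]
        for c in config.concentrations:
            effect = config.max_inhibition * c**config.hill / (
                c**config.hill + config.ic50**config.hill
            )
            # ic50 parameterizes the measured percent-effect curve, so map the
            # target effect back to the inhibition fraction that produces it
            inh = inhibition_for_effect(scfg, config.stimulus, effect)
            wells.append(("DRUG", "test", inh, c))
        for k, (compound, role, inhibition, conc) in enumerate(wells):
            if compound:
                well = f"S1-{compound}@{conc}"
            else:
                well = f"S1-{'POS' if role == 'positive_control' else 'NEG'}{k // 2 + 1}"
            for tech in range(1, config.technical_replicates + 1):
                seed = np.random.SeedSequence(
                    [int(config.seed), 0xD05E, bio, k, tech]
                ).generate_state(1)[0]
                md = {
                    "plate": plate,
                    "well": well,
                    "role": role,
                    "compound": compound,
                    "set": "S1",
                    "concentration": conc,
                    "technical_replicate": tech,
                    "biological_replicate": bio,
                }
                spectra.append(
                    generate_spectrum(scfg, config.stimulus, int(seed), inhibition, md)
                )
                rows.append(
                    {
                        "plate": plate,
                        "well": well,
                        "role": role,
                        "compound": compound,
                        "concentration": conc,
                        "set": "S1",
                        "technical_replicate": tech,
                        "biological_replicate": bio,
                    }
                )
    return spectra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thermal profiling
# ---------------------------------------------------------------------------


@dataclass
class ProteinMeltSpec:
    """True melting behaviour of one protein: Tm per condition plus shape."""

    name: str
    tm: dict          # condition label -> true Tm (degC)
    slope_b: float = 25.0
    plateau: float = 0.02

    def __post_init__(self) -> None:
        if not self.tm:
            raise ConfigError(f"protein {self.name!r} has no conditions")
        if not 0 <= self.plateau < 0.5:
            raise ConfigError("plateau must be in [0, 0.5)")


@dataclass
class TPPSimConfig:
    """Thermal-profiling simulation: proteins x temperatures x conditions x replicates.

    Defaults follow the experimental design: the 8-point 40-68 degC
    temperature ramp, two drug conditions, four replicates, 10% multiplicative
    abundance noise, and a per-replicate biological Tm jitter of 0.5 degC.
    """

    proteins: list = field(default_factory=list)
    temperatures: tuple = DEFAULT_TEMPERATURES
    replicates: int = 4
    abundance_noise_cv: float = 0.10
    tm_jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        if len(temps) < 2 or not np.all(np.diff(temps) > 0):
            raise ConfigError("temperatures must be strictly increasing")
        if self.replicates < 2:
            raise ConfigError("need >= 2 replicates")


def simulate_tpp(config: TPPSimConfig) -> pd.DataFrame:
    """Long-format relative-abundance table (protein, condition, replicate, T).

    Each trace is the melt sigmoid for the replicate's jittered Tm, evaluated
    at the design temperatures and multiplied by independent log-normal noise;
    values are relative to the lowest temperature (expected 1 there).
    """
    temps = np.asarray(config.temperatures, dtype=float)
    rows = []
    for ip, prot in enumerate(config.proteins):
        for ic, (cond, tm_true) in enumerate(sorted(prot.tm.items())):
            for rep in range(1, config.replicates + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(config.seed), ip, ic, rep]).generate_state(4)
                )
                tm_rep = tm_true + rng.normal(0.0, config.tm_jitter_sd)
                a, b = params_for_tm(tm_rep, prot.slope_b, prot.plateau)
                trace = melt_model(temps, a, b, prot.plateau)
                trace = trace / trace[0]
                trace = trace * _lognormal_factor(rng, config.abundance_noise_cv, len(temps))
                for t, v in zip(temps, trace):
                    rows.append(
                        {
                            "protein": prot.name,
                            "condition": cond,
                            "replicate": rep,
                            "temperature": t,
                            "rel_abundance": v,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_itdr(
    ec50: float = 4.6,
    hill: float = 1.0,
    baseline_fraction: float = 0.1,
    max_fraction: float = 0.9,
    concentrations=(0.1, 0.5, 1.0, 5.0, 10.0),
    noise_cv: float = 0.10,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Isothermal dose-response: soluble fraction vs concentration at one T.

    The soluble fraction follows the rising logistic
    ``b0 + (bmax - b0) / (1 + ec50 / c)`` (Hill slope ``hill`` generalizes
    the denominator) with multiplicative log-normal noise.  Concentrations in
    uM; ``n_replicates`` independent series emulate independent experiments.
    """
    if ec50 <= 0:
        raise ConfigError("ec50 must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ConfigError("concentrations must be >= 0")
    rows = []
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 0x17D8, rep]).generate_state(4)
        )
        with np.errstate(divide="ignore"):
            ratio = np.where(conc > 0, (ec50 / np.where(conc > 0, conc, 1.0)) ** hill, np.inf)
        y = baseline_fraction + (max_fraction - baseline_fraction) / (1.0 + ratio)
        y = y * _lognormal_factor(rng, noise_cv, len(conc))
        for c, v in zip(conc, y):
            rows.append({"concentration": c, "replicate": rep, "soluble_fraction": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets parameterized from the reported assay characterization
# ---------------------------------------------------------------------------


def p38a_tpp_preset(seed: int = 0) -> TPPSimConfig:
    """p38alpha-like protein: +6 degC shift under nilotinib vs imatinib."""
    return TPPSimConfig(
        proteins=[ProteinMeltSpec("p38a", {"imatinib": 50.8, "nilotinib": 56.8})],
        seed=seed,
    )


def mk3_tpp_preset(seed: int = 0) -> TPPSimConfig:
    """MK3-like protein: +2.5 degC shift under nilotinib vs imatinib."""
    return TPPSimConfig(
        proteins=[ProteinMeltSpec("MK3", {"imatinib": 51.0, "nilotinib": 53.5})],
        seed=seed,
    )


def cetsa_preset(seed: int = 0) -> TPPSimConfig:
    """Targeted (western-blot) thermal shift of p38alpha in four conditions."""
    return TPPSimConfig(
        proteins=[
            ProteinMeltSpec(
                "p38a",
                {"DMSO": 50.3, "LPS": 50.2, "nilotinib": 60.7, "imatinib": 50.8},
            )
        ],
        replicates=4,
        abundance_noise_cv=0.05,
        tm_jitter_sd=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------

_CONFIG_TYPES = {
    "SpectrumSimConfig": SpectrumSimConfig,
    "ScreenSimConfig": ScreenSimConfig,
    "DoseSeriesSimConfig": DoseSeriesSimConfig,
    "TPPSimConfig": TPPSimConfig,
}


def config_to_yaml(config, path) -> None:
    """Serialize any Sim config (including nested peak/protein specs) to YAML."""
    payload = {"type": type(config).__name__, "config": asdict(config)}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path):
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    cls = _CONFIG_TYPES[payload["type"]]
    cfg = payload["config"]
    if cls is SpectrumSimConfig:
        cfg["peak_panel"] = [PeakSpec(**p) for p in cfg.get("peak_panel", [])]
        cfg["mass_range"] = tuple(cfg["mass_range"])
    if cls is TPPSimConfig:
        cfg["proteins"] = [ProteinMeltSpec(**p) for p in cfg.get("proteins", [])]
        cfg["temperatures"] = tuple(cfg["temperatures"])
    if cls is DoseSeriesSimConfig:
        cfg["concentrations"] = tuple(cfg["concentrations"])
    return cls(**cfg)
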