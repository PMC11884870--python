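"""Synthetic multimodal studies with a planted latent prosociality factor.

The generator emulates the structure of a games + multimodal-MRI study: a
single standardized latent trait ``theta`` (prosociality) drives

* behavioral decisions in the 15 economic games (prosocial variables load
  positively, aggression/punishment variables negatively),
* parcel-level cortical metrics (thickness up, T1w/T2w myelin down; neurite
  indices carry no planted signal) and subcortical volumes (ventricles down,
  corpus callosum and reward/limbic structures up),
* functional and structural connectivity matrices, where homotopic
  (same-parcel left-right) edges and within-module edges strengthen with
  ``theta`` — which raises clustering/local efficiency and shortens nodal
  path lengths in the thresholded graphs.

Confound effects (age, sex, intracranial volume, transmit amplitude, ...)
and additive noise are superimposed, and the full ground truth is kept so
recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .games import VariableSpec, default_variable_schema, PROSOCIAL, AGGRESSION

__all__ = [
    "SimulationConfig",
    "LatentGroundTruth",
    "SyntheticStudy",
    "simulate_study",
    "cortical_labels",
    "subcortical_labels",
    "SUBCORTICAL_LABELS",
]

# Standard FreeSurfer aseg structure names (41 entries), including the named
# ventricles and the five corpus-callosum subregions.
SUBCORTICAL_LABELS: tuple[str, ...] = (
    "Left-Lateral-Ventricle", "Right-Lateral-Ventricle",
    "Left-Inf-Lat-Vent", "Right-Inf-Lat-Vent",
    "3rd-Ventricle", "4th-Ventricle", "5th-Ventricle",
    "Left-Cerebellum-White-Matter", "Right-Cerebellum-White-Matter",
    "Left-Cerebellum-Cortex", "Right-Cerebellum-Cortex",
    "Left-Thalamus-Proper", "Right-Thalamus-Proper",
    "Left-Caudate", "Right-Caudate",
    "Left-Putamen", "Right-Putamen",
    "Left-Pallidum", "Right-Pallidum",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Amygdala", "Right-Amygdala",
    "Left-Accumbens-area", "Right-Accumbens-area",
    "Left-VentralDC", "Right-VentralDC",
    "Left-vessel", "Right-vessel",
    "Left-choroid-plexus", "Right-choroid-plexus",
    "Brain-Stem", "CSF", "Optic-Chiasm",
    "WM-hypointensities", "non-WM-hypointensities",
    "CC_Posterior", "CC_Mid_Posterior", "CC_Central", "CC_Mid_Anterior",
    "CC_Anterior",
)

VENTRICLES = tuple(s for s in SUBCORTICAL_LABELS if "Vent" in s and "VentralDC" not in s)
CORPUS_CALLOSUM = tuple(s for s in SUBCORTICAL_LABELS if s.startswith("CC_"))
POSITIVE_VOLUMES = (
    "Left-Accumbens-area", "Right-Accumbens-area",
    "Left-Amygdala", "Right-Amygdala",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Pallidum", "Right-Pallidum",
)

CORTICAL_METRICS = ("thickness", "myelin", "ndi", "odi")

# Per-metric baseline level, regional spread of the baseline, and residual
# noise SD (plausible units: mm, T1w/T2w ratio, NODDI fractions).
_METRIC_SCALES = {
    "thickness": (2.5, 0.20, 0.10),
    "myelin": (1.45, 0.15, 0.08),
    "ndi": (0.25, 0.03, 0.020),
    "odi": (0.35, 0.04, 0.030),
}
# Planted sign of theta's effect per cortical metric (0 = no planted signal).
_METRIC_SIGNS = {"thickness": +1.0, "myelin": -1.0, "ndi": 0.0, "odi": 0.0}


def cortical_labels(n_per_hemi: int = 180) -> list[str]:
    """Parcel labels with L_/R_ hemisphere prefixes (left hemisphere first)."""
    return [f"L_P{i + 1:03d}" for i in range(n_per_hemi)] + [
        f"R_P{i + 1:03d}" for i in range(n_per_hemi)
    ]


def subcortical_labels() -> list[str]:
    return list(SUBCORTICAL_LABELS)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``snr`` scales every planted theta effect relative to each variable's
    noise SD; ``snr=0`` produces a pure-noise (null) study. The connectivity
    increments are expressed on the correlation scale for the functional
    matrices and as rate multipliers for the streamline counts.
    """

    n_parcels_per_hemi: int = 180
    n_modules: int = 12
    snr: float = 1.0
    behavioral_noise_sd: float = 1.0
    # functional connectivity (correlation scale)
    fc_background: float = 0.05
    fc_module: float = 0.18
    fc_homotopic: float = 0.35
    fc_noise_sd: float = 0.10
    fc_theta_homotopic: float = 0.10
    fc_theta_module: float = 0.06
    # structural connectivity (expected streamline counts)
    sc_rate: float = 2000.0
    sc_background: float = 0.01
    sc_module: float = 0.05
    sc_homotopic: float = 0.12
    sc_theta_homotopic: float = 0.80  # relative modulation of homotopic rate
    sc_theta_module: float = 0.25  # relative modulation of module rate
    sc_dispersion: float = 1.0  # gamma-Poisson overdispersion shape (lower = noisier)
    sc_shortcut_frac: float = 0.0  # optional long-range shortcut pairs (off by default)
    sc_shortcut: float = 0.025  # base shortcut rate (relative units)
    sc_theta_shortcut: float = 0.6  # relative modulation of shortcut rates
    confound_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.behavioral_noise_sd <= 0:
            raise ValueError("behavioral_noise_sd must be positive")
        if self.n_parcels_per_hemi < 2:
            raise ValueError("need at least 2 parcels per hemisphere")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")


@dataclass
class LatentGroundTruth:
    """Planted effects, kept for recovery scoring."""

    theta: np.ndarray  # (n,), standardized
    beta_game: pd.Series  # effect of theta per behavioral variable (latent scale)
    gamma_cortical: pd.DataFrame  # parcels x 4 metrics, effect per unit theta
    gamma_volume: pd.Series  # 41 subcortical volumes
    homotopic_fc: pd.Series  # per-pair functional increment per unit theta
    homotopic_sc: pd.Series  # per-pair structural rate modulation per unit theta
    confound_effects: dict
    noise_sd: dict
    class_signs: dict = field(default_factory=dict)

    def regional_signatures(self) -> dict[str, pd.Series]:
        """Per-region planted effect vectors for metric classes with
        explicit regional signal (used for signature-recovery scoring)."""
        return {
            "thickness": self.gamma_cortical["thickness"],
            "myelin": self.gamma_cortical["myelin"],
            "interhemispheric_f": self.homotopic_fc,
            "interhemispheric_s": self.homotopic_sc,
        }


@dataclass
class SyntheticStudy:
    behavioral: pd.DataFrame
    structure: pd.DataFrame
    covariates: pd.DataFrame
    functional: np.ndarray  # (n, nodes, nodes) float32, correlation-like
    structural_counts: np.ndarray  # (n, nodes, nodes) int32 streamline counts
    waytotal: np.ndarray  # (n, nodes)
    node_labels: list[str]
    schema: list[VariableSpec]
    truth: LatentGroundTruth
    seed: int
    config: SimulationConfig

    @property
    def n_participants(self) -> int:
        return len(self.behavioral)

    def write(self, outdir: str | Path, *, matrices: bool = False) -> None:
        """Write TSV tables (and optionally per-participant dense matrices)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.behavioral.to_csv(outdir / "behavioral.tsv", sep="\t")
        self.structure.to_csv(outdir / "structure.tsv", sep="\t")
        self.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
        truth = {
            "theta": self.truth.theta.tolist(),
            "beta_game": self.truth.beta_game.to_dict(),
            "gamma_volume": self.truth.gamma_volume.to_dict(),
            "class_signs": self.truth.class_signs,
            "seed": self.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        if matrices:
            mdir = outdir / "matrices"
            mdir.mkdir(exist_ok=True)
            for i, pid in enumerate(self.behavioral.index):
                np.savetxt(mdir / f"{pid}_functional.tsv",
                           self.functional[i], delimiter="\t", fmt="%.6f")
                np.savetxt(mdir / f"{pid}_structural_counts.tsv",
                           self.structural_counts[i], delimiter="\t", fmt="%d")
            np.savetxt(mdir / "waytotal.tsv", self.waytotal, delimiter="\t", fmt="%d")


# ---------------------------------------------------------------------------


def _module_assignment(n_per_hemi: int, n_modules: int) -> np.ndarray:
    """Mirror-symmetric module labels: parcel i gets the same module in both
    hemispheres, modules are contiguous blocks of parcels."""
    per_hemi = np.minimum((np.arange(n_per_hemi) * n_modules) // n_per_hemi,
                          n_modules - 1)
    return np.concatenate([per_hemi, per_hemi])


def _variable_midspan(v: VariableSpec) -> tuple[float, float]:
    mid = 0.5 * (v.lo + v.hi)
    span = v.hi - v.lo
    return mid, span


def simulate_study(
    n_participants: int = 217,
    seed: int = 0,
    config: SimulationConfig | None = None,
    schema: list[VariableSpec] | None = None,
) -> SyntheticStudy:
    """Generate one complete synthetic study.

    Identical ``(n_participants, seed, config)`` always produces a
    bit-identical study. ``n_participants`` defaults to 217, the size of the
    analyzed complete-case sample.
    """
    if n_participants < 4:
        raise ValueError("need at least 4 participants")
    cfg = config or SimulationConfig()
    schema = schema if schema is not None else default_variable_schema()

    ss = np.random.SeedSequence(seed)
    (ss_cov, ss_theta, ss_truth, ss_behav, ss_struct,
     ss_fc, ss_sc) = ss.spawn(7)

    n = n_participants
    pid = pd.Index([f"sub-{i + 1:04d}" for i in range(n)], name="participant")

    # --- covariates -------------------------------------------------------
    rng = np.random.default_rng(ss_cov)
    age = rng.uniform(20, 60, n)
    sex = rng.integers(0, 2, n).astype(float)  # 0 = female, 1 = male
    handedness = np.clip(rng.normal(75, 35, n), -100, 100)  # Edinburgh score
    icv = rng.normal(1.45e6, 1.2e5, n) + 8e4 * sex  # mm^3
    transmit = rng.normal(250.0, 15.0, n)  # transmit reference amplitude (V)
    education = rng.integers(0, 2, n).astype(float)  # undergraduate degree
    income = rng.integers(1, 8, n).astype(float)  # 7-point ordinal
    iq = rng.normal(100, 15, n)
    gonogo_fa = np.clip(rng.normal(5, 2.5, n), 0, None).round()
    covariates = pd.DataFrame(
        {
            "age": age, "sex": sex, "handedness": handedness, "icv": icv,
            "transmit_amplitude": transmit, "education": education,
            "income": income, "iq": iq, "gonogo_false_alarms": gonogo_fa,
        },
        index=pid,
    )
    age_z = (age - 40.0) / 11.5
    icv_z = (icv - 1.49e6) / 1.2e5
    transmit_z = (transmit - 250.0) / 15.0

    # --- latent trait, standardized exactly -------------------------------
    rng = np.random.default_rng(ss_theta)
    theta = rng.standard_normal(n)
    theta = (theta - theta.mean()) / theta.std()

    # --- planted effect sizes --------------------------------------------
    rng = np.random.default_rng(ss_truth)
    snr = cfg.snr
    dir_sign = np.array(
        [1.0 if v.direction == PROSOCIAL else -1.0 if v.direction == AGGRESSION else 0.0
         for v in schema]
    )
    beta = pd.Series(dir_sign * snr * cfg.behavioral_noise_sd,
                     index=[v.name for v in schema])

    H = cfg.n_parcels_per_hemi
    labels = cortical_labels(H)
    parcels = [lb[2:] for lb in labels[:H]]

    gamma_cort = {}
    w_thick = None
    for metric in CORTICAL_METRICS:
        _, _, noise_sd = _METRIC_SCALES[metric]
        w = rng.uniform(0.2, 1.0, H)  # shared across hemispheres
        if metric == "thickness":
            w_thick = w
        elif metric == "myelin":
            # myelin and thickness regional signatures share a component
            # (with opposite planted signs), so their loading maps are
            # mildly anti-correlated across regions
            w = 0.35 * w_thick + 0.65 * w
        gamma_cort[metric] = _METRIC_SIGNS[metric] * snr * noise_sd * np.concatenate([w, w])
    gamma_cortical = pd.DataFrame(gamma_cort, index=labels)

    vol_sign = np.zeros(len(SUBCORTICAL_LABELS))
    for i, s in enumerate(SUBCORTICAL_LABELS):
        if s in VENTRICLES:
            vol_sign[i] = -1.0
        elif s in CORPUS_CALLOSUM or s in POSITIVE_VOLUMES:
            vol_sign[i] = +1.0
    vol_w = rng.uniform(0.4, 1.0, len(SUBCORTICAL_LABELS))
    # volume noise scales with baseline; gamma expressed on the noise scale below

    h_fc = rng.uniform(0.3, 1.0, H) * cfg.fc_theta_homotopic * snr
    h_sc = rng.uniform(0.3, 1.0, H) * cfg.sc_theta_homotopic * snr
    module = _module_assignment(H, cfg.n_modules)
    mod_w = rng.uniform(0.3, 1.0, cfg.n_modules)

    # --- behavioral table -------------------------------------------------
    rng = np.random.default_rng(ss_behav)
    conf_age_b = rng.normal(0, 0.15, len(schema)) * cfg.confound_scale
    conf_sex_b = rng.normal(0, 0.20, len(schema)) * cfg.confound_scale
    noise_b = rng.normal(0, cfg.behavioral_noise_sd, (n, len(schema)))
    latent = (
        np.outer(theta, beta.to_numpy())
        + np.outer(age_z, conf_age_b)
        + np.outer(sex, conf_sex_b)
        + noise_b
    )
    behav = np.empty((n, len(schema)))
    for j, v in enumerate(schema):
        mid, span = _variable_midspan(v)
        if v.binary:
            behav[:, j] = (latent[:, j] > 0).astype(float)
        else:
            raw = mid + (span / 4.0) * latent[:, j]
            raw = np.clip(raw, v.lo, v.hi)
            behav[:, j] = v.lo + np.round((raw - v.lo) / v.step) * v.step
    behavioral = pd.DataFrame(behav, index=pid, columns=[v.name for v in schema])

    # --- cortical metrics + subcortical volumes ---------------------------
    rng = np.random.default_rng(ss_struct)
    struct_cols: dict[str, np.ndarray] = {}
    for metric in CORTICAL_METRICS:
        base, base_spread, noise_sd = _METRIC_SCALES[metric]
        baseline = base + rng.normal(0, base_spread, 2 * H)
        eff = gamma_cortical[metric].to_numpy()
        age_coef = -0.25 * noise_sd if metric in ("thickness", "ndi") else 0.1 * noise_sd
        conf = (
            np.outer(age_z, np.full(2 * H, age_coef))
            + np.outer(sex, rng.normal(0, 0.1 * noise_sd, 2 * H))
            + (np.outer(transmit_z, rng.normal(0, 0.3 * noise_sd, 2 * H))
               if metric == "myelin" else 0.0)
        ) * cfg.confound_scale
        vals = baseline[None, :] + np.outer(theta, eff) + conf + rng.normal(0, noise_sd, (n, 2 * H))
        for k, lb in enumerate(labels):
            struct_cols[f"{metric}_{lb}"] = vals[:, k]

    vol_base = np.array(
        [1.2e4 if s in VENTRICLES else
         600.0 if s in CORPUS_CALLOSUM else
         4.0e3 for s in SUBCORTICAL_LABELS]
    )
    vol_noise = 0.08 * vol_base
    gamma_volume = pd.Series(vol_sign * snr * vol_noise * vol_w,
                             index=list(SUBCORTICAL_LABELS))
    age_v = np.array([0.3 if s in VENTRICLES else -0.25 for s in SUBCORTICAL_LABELS]) * vol_noise
    vol_vals = (
        vol_base[None, :]
        + np.outer(theta, gamma_volume.to_numpy())
        + (np.outer(age_z, age_v) + np.outer(icv_z, 0.5 * vol_noise)) * cfg.confound_scale
        + rng.normal(0, 1.0, (n, len(vol_base))) * vol_noise
    )
    for k, s in enumerate(SUBCORTICAL_LABELS):
        struct_cols[f"volume_{s}"] = vol_vals[:, k]
    structure = pd.DataFrame(struct_cols, index=pid)

    # --- connectivity matrices -------------------------------------------
    nodes = 2 * H
    same_module = module[:, None] == module[None, :]
    hom = np.zeros((nodes, nodes), dtype=bool)
    idx = np.arange(H)
    hom[idx, idx + H] = True
    hom[idx + H, idx] = True
    mod_w_edge = mod_w[module][:, None] * 0.5 + mod_w[module][None, :] * 0.5

    fc_base = np.full((nodes, nodes), cfg.fc_background)
    fc_base[same_module] += cfg.fc_module
    fc_base[hom] = cfg.fc_background + cfg.fc_homotopic
    fc_gain = np.zeros((nodes, nodes))
    fc_gain[same_module] = cfg.fc_theta_module * snr * mod_w_edge[same_module]
    fc_gain[hom] = np.concatenate([h_fc, h_fc])  # symmetric by construction

    sc_lam = np.full((nodes, nodes), cfg.sc_background)
    sc_lam[same_module] += cfg.sc_module
    sc_lam[hom] += cfg.sc_homotopic
    sc_gain = np.zeros((nodes, nodes))
    sc_gain[same_module] = cfg.sc_module * cfg.sc_theta_module * snr * mod_w_edge[same_module]
    sc_gain[hom] = cfg.sc_homotopic * np.concatenate([h_sc, h_sc])
    # long-range shortcuts: a fixed random set of cross-module tracts whose
    # strength rises with theta, shortening structural path lengths
    rng_t2 = np.random.default_rng(ss_truth.spawn(1)[0])
    cross_i, cross_j = np.nonzero(np.triu(~same_module & ~hom, k=1))
    n_short = int(round(cfg.sc_shortcut_frac * cross_i.size))
    if n_short > 0:
        pick = rng_t2.choice(cross_i.size, size=n_short, replace=False)
        si, sj = cross_i[pick], cross_j[pick]
        sw = rng_t2.uniform(0.3, 1.0, n_short)
        sc_lam[si, sj] += cfg.sc_shortcut
        sc_lam[sj, si] += cfg.sc_shortcut
        inc = cfg.sc_shortcut * cfg.sc_theta_shortcut * snr * sw
        sc_gain[si, sj] += inc
        sc_gain[sj, si] += inc

    age_fc = -0.015 * cfg.confound_scale

    rng_fc = np.random.default_rng(ss_fc)
    rng_sc = np.random.default_rng(ss_sc)
    functional = np.empty((n, nodes, nodes), dtype=np.float32)
    structural = np.empty((n, nodes, nodes), dtype=np.int32)
    waytotal = np.empty((n, nodes), dtype=np.int64)
    diag = np.arange(nodes)
    for i in range(n):
        e = rng_fc.normal(0, cfg.fc_noise_sd, (nodes, nodes))
        w = fc_base + theta[i] * fc_gain + age_fc * age_z[i] + (e + e.T) * (0.5 ** 0.5)
        np.clip(w, -0.999, 0.999, out=w)
        w[diag, diag] = 1.0
        functional[i] = w

        lam = cfg.sc_rate * np.clip(sc_lam + theta[i] * sc_gain, 1e-4, None)
        # gamma-Poisson: tractography counts are overdispersed, which makes
        # the edge ranking (and hence the thresholded topology) responsive
        # to the planted modulation rather than frozen by tiny Poisson noise
        eps = rng_sc.gamma(cfg.sc_dispersion, 1.0 / cfg.sc_dispersion,
                           (nodes, nodes))
        lam = lam * eps
        lam[diag, diag] = 0.0
        counts = rng_sc.poisson(lam)
        structural[i] = counts
        row = counts.sum(axis=1)
        waytotal[i] = row + rng_sc.poisson(0.3 * np.maximum(row, 1))

    homotopic_index = pd.Index(parcels, name="parcel")
    truth = LatentGroundTruth(
        theta=theta,
        beta_game=beta,
        gamma_cortical=gamma_cortical,
        gamma_volume=gamma_volume,
        homotopic_fc=pd.Series(h_fc, index=homotopic_index),
        homotopic_sc=pd.Series(h_sc, index=homotopic_index),
        confound_effects={"behavioral_age": conf_age_b.tolist(),
                          "behavioral_sex": conf_sex_b.tolist()},
        noise_sd={m: _METRIC_SCALES[m][2] for m in CORTICAL_METRICS}
        | {"behavioral": cfg.behavioral_noise_sd},
        class_signs={
            "interhemispheric_f": +1, "interhemispheric_s": +1,
            "myelin": -1, "thickness": +1,
            "path_length_f": -1, "path_length_s": -1,
            "clustering_f": +1, "local_efficiency_f": +1,
            "ventricle": -1, "corpus_callosum": +1,
        },
    )
    return SyntheticStudy(
        behavioral=behavioral,
        structure=structure,
        covariates=covariates,
        functional=functional,
        structural_counts=structural,
        waytotal=waytotal,
        node_labels=labels,
        schema=schema,
        truth=truth,
        seed=seed,
        config=cfg,
    )


def noiseless_behavioral_mean(theta_value: float, v: VariableSpec, beta: float) -> float:
    """Expected decision for one variable at a given theta with no noise or
    confounds — used to check monotonicity of the generator."""
    latent = beta * theta_value
    if v.binary:
        return float(latent > 0)
    mid, span = _variable_midspan(v)
    raw = float(np.clip(mid + (span / 4.0) * latent, v.lo, v.hi))
    return v.lo + round((raw - v.lo) / v.step) * v.step
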