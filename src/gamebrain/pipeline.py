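"""End-to-end pipeline: simulate -> preprocess -> connectome -> reduce ->
fit -> permutation test -> cross-loadings -> report.

A single master seed expands into per-stage substreams keyed by stage name
(CRC32 of the name mixed into a ``SeedSequence``), so any stage can be
re-run in isolation and the full run is deterministic end to end.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from . import inference, loadings, preprocess, reduction, smcca, synth

__all__ = ["RunConfig", "run_pipeline", "run_robustness", "stage_seed"]


def stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Deterministic named substream of the master seed."""
    return np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])


def _stage_int(master: int, stage: str) -> int:
    return int(stage_seed(master, stage).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All pipeline knobs in one validated, hashable place."""

    seed: int = 0
    n_participants: int = 217
    k_games: int = 30
    k_brain: int = 60
    penalty_fraction: float | None = 0.5  # None => select from the grid
    penalty_grid: tuple[float, ...] = tuple(np.linspace(0.1, 0.9, 10).round(8))
    n_perm: int = 1000
    n_perm_select: int = 100
    confounds: str = "base"  # base | extended
    standardize: bool = True
    snr: float = 1.0
    n_parcels_per_hemi: int = 180
    use_absolute: bool = True
    max_candidates: int = 20
    n_sources: int | None = 60
    robustness_k: tuple[int, ...] = (60, 70, 80)

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("n_participants must be at least 4")
        if self.confounds not in ("base", "extended"):
            raise ValueError("confounds must be 'base' or 'extended'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if not (0 < self.k_games and 0 < self.k_brain):
            raise ValueError("component counts must be positive")
        if self.penalty_fraction is not None and not (0 < self.penalty_fraction <= 1):
            raise ValueError("penalty_fraction must be in (0, 1]")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _orient_to_prosocial(results: smcca.SparseMCCAResults,
                         blocks: dict[str, preprocess.FeatureSet]) -> None:
    """Fix the global sign so prosocial-tagged game variables load
    positively on the brain variates (one global flip; correlations are
    untouched)."""
    brain_sets = [c for c in results.variates.columns if c != "games"]
    mean_brain = results.variates[brain_sets].mean(axis=1)
    if mean_brain.std() == 0:
        return
    r = loadings.cross_loadings(blocks["games"].data, mean_brain)
    direction = blocks["games"].metadata["direction"]
    pros = r[direction == "prosocial"].mean()
    if pros < 0:
        results.orient(-1)


def _recovery_metrics(report: loadings.CrossLoadingReport,
                      truth: synth.LatentGroundTruth) -> dict:
    """Score planted-signal recovery: sign agreement of class mean loadings
    and correlation between estimated and planted regional signatures."""
    means = report.class_summaries.set_index("metric_class")["mean"]
    sign_match = {}
    for cls, sign in truth.class_signs.items():
        if cls in means.index:
            sign_match[cls] = bool(np.sign(means[cls]) == np.sign(sign))
    sig_corr = {}
    brain = report.brain_loadings
    for cls, planted in truth.regional_signatures().items():
        est = brain[brain["metric_class"] == cls].set_index("region")["loading"]
        common = est.index.intersection(planted.index)
        a, b = est.loc[common], planted.loc[common]
        if len(common) >= 3 and a.std() > 0 and b.std() > 0:
            sig_corr[cls] = float(np.corrcoef(a, b)[0, 1])
    return {"sign_match": sign_match, "signature_correlation": sig_corr}


def _score_sets(blocks: dict[str, preprocess.FeatureSet], k_games: int,
                k_brain: int, standardize: bool) -> tuple[dict, dict]:
    pcs = {}
    sets = {}
    for name, fs in blocks.items():
        k = k_games if name == "games" else k_brain
        k = min(k, fs.data.shape[0] - 1, fs.data.shape[1])
        model = reduction.pca(fs.data, k, standardize=standardize)
        pcs[name] = model
        sets[name] = model.scores
    return sets, pcs


def run_pipeline(config: RunConfig,
                 study: synth.SyntheticStudy | None = None) -> dict:
    """Execute every stage in order and return the run report.

    The report carries the canonical correlations per set pair, both
    permutation p-values, penalty diagnostics, the loading summaries, and —
    when ground truth is available — recovery metrics. Intermediate objects
    are attached under ``"objects"`` for programmatic use.
    """
    t0 = time.perf_counter()
    timing = {}
    cfg = config

    if study is None:
        sim_cfg = synth.SimulationConfig(
            n_parcels_per_hemi=cfg.n_parcels_per_hemi, snr=cfg.snr)
        study = synth.simulate_study(cfg.n_participants,
                                     _stage_int(cfg.seed, "simulate"), sim_cfg)
    timing["simulate"] = time.perf_counter() - t0

    t = time.perf_counter()
    blocks = preprocess.build_feature_sets(
        study, confounds=cfg.confounds, max_candidates=cfg.max_candidates,
        n_sources=cfg.n_sources, use_absolute=cfg.use_absolute)
    timing["preprocess_connectome"] = time.perf_counter() - t

    t = time.perf_counter()
    sets, pcs = _score_sets(blocks, cfg.k_games, cfg.k_brain, cfg.standardize)
    timing["reduce"] = time.perf_counter() - t

    t = time.perf_counter()
    penalty_diag = None
    if cfg.penalty_fraction is None:
        sel = smcca.select_penalties(
            sets, list(cfg.penalty_grid), n_perm=cfg.n_perm_select,
            seed=_stage_int(cfg.seed, "select_penalties"))
        fraction = sel.fraction
        penalty_diag = sel.table.to_dict(orient="list")
    else:
        fraction = cfg.penalty_fraction
    model = smcca.SparseMCCA(sets, penalty_fractions=fraction)
    results = model.fit()
    _orient_to_prosocial(results, blocks)
    timing["fit"] = time.perf_counter() - t

    t = time.perf_counter()
    perm = inference.permutation_test(
        sets, fraction, n_perm=cfg.n_perm,
        seed=_stage_int(cfg.seed, "permutation_test"))
    timing["permtest"] = time.perf_counter() - t

    t = time.perf_counter()
    report = loadings.build_report(blocks, results.variates)
    timing["loadings"] = time.perf_counter() - t

    recovery = _recovery_metrics(report, study.truth) if study.truth else None

    pair_cor = {
        f"games~{name}": float(results.pairwise_correlations.loc["games", name])
        for name in results.set_names if name != "games"
    }
    out = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_participants": study.n_participants,
        "n_brain_features": int(sum(
            blocks[b].n_features for b in blocks if b != "games")),
        "penalty_fraction": fraction,
        "penalty_diagnostics": penalty_diag,
        "sum_cor": results.sum_cor,
        "pairwise_correlations": pair_cor,
        "p_value": perm.p_value,
        "p_value_add_one": perm.p_value_add_one,
        "variance_explained": {
            name: float(m.variance_explained.sum()) for name, m in pcs.items()},
        "class_summaries": report.class_summaries.to_dict(orient="list"),
        "myelin_thickness_r": report.myelin_thickness_r,
        "myelin_thickness_ci": list(report.myelin_thickness_ci),
        "recovery": recovery,
        "timing_s": {k: round(v, 3) for k, v in timing.items()},
        "objects": {
            "study": study, "blocks": blocks, "pcs": pcs,
            "results": results, "permutation": perm, "report": report,
        },
    }
    return out


def run_robustness(config: RunConfig,
                   study: synth.SyntheticStudy | None = None,
                   blocks: dict[str, preprocess.FeatureSet] | None = None) -> dict:
    """Re-run the fit at several brain component counts (default 60/70/80)
    on one study and measure loading concordance across K.

    The PCA is computed once at the largest K; smaller-K score sets are its
    leading columns (principal components are nested). Pre-assembled
    ``blocks`` may be supplied to skip the connectome stage."""
    cfg = config
    if blocks is None:
        if study is None:
            sim_cfg = synth.SimulationConfig(
                n_parcels_per_hemi=cfg.n_parcels_per_hemi, snr=cfg.snr)
            study = synth.simulate_study(cfg.n_participants,
                                         _stage_int(cfg.seed, "simulate"), sim_cfg)
        blocks = preprocess.build_feature_sets(
            study, confounds=cfg.confounds, max_candidates=cfg.max_candidates,
            n_sources=cfg.n_sources, use_absolute=cfg.use_absolute)
    kmax = max(cfg.robustness_k)
    sets_full, _ = _score_sets(blocks, cfg.k_games, kmax, cfg.standardize)

    fraction = cfg.penalty_fraction if cfg.penalty_fraction is not None else 0.5
    runs = {}
    vectors = {}
    for k in cfg.robustness_k:
        sets = {
            name: (df if name == "games" else df.iloc[:, :k])
            for name, df in sets_full.items()
        }
        model = smcca.SparseMCCA(sets, penalty_fractions=fraction)
        res = model.fit()
        _orient_to_prosocial(res, blocks)
        rep = loadings.build_report(blocks, res.variates)
        runs[k] = {
            "sum_cor": res.sum_cor,
            "class_summaries": rep.class_summaries.to_dict(orient="list"),
        }
        vectors[k] = rep.brain_loadings["loading"]

    ks = list(cfg.robustness_k)
    conc = {}
    for i, ka in enumerate(ks):
        for kb in ks[i + 1:]:
            a, b = vectors[ka].align(vectors[kb], join="inner")
            conc[f"K{ka}~K{kb}"] = float(np.corrcoef(a, b)[0, 1])
    return {"runs": runs, "concordance": conc,
            "median_concordance": float(np.median(list(conc.values()))),
            "objects": {"study": study, "blocks": blocks}}
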