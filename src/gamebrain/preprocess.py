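"""Confound residualization and assembly of the four analysis blocks.

Every variable is replaced by its least-squares residual on an intercept
plus confounds before any multivariate analysis: behavioral variables on
age and sex; brain variables additionally on handedness, intracranial
volume and transmit reference amplitude. An extended-confound mode adds
education, income, IQ and go/no-go false alarms on top of (never instead
of) the base set. Missing covariate values are an error — the analysis is
complete-case by design.

The brain features enumerate to 5,441 columns at full scale: 4 cortical
metrics x 360 parcels + 41 subcortical volumes (structure block), and per
connectivity modality 5 nodal graph measures x 360 + 180 homotopic pairs
(functional and structural blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import connectome
from .synth import SyntheticStudy, CORTICAL_METRICS, SUBCORTICAL_LABELS

__all__ = [
    "FeatureSet",
    "residualize",
    "confound_columns",
    "connectivity_features",
    "assemble_brain_blocks",
    "build_feature_sets",
]

BASE_CONFOUNDS = ("age", "sex")
BRAIN_CONFOUNDS = ("age", "sex", "handedness", "icv", "transmit_amplitude")
EXTENDED_EXTRA = ("education", "income", "iq", "gonogo_false_alarms")

GRAPH_MEASURES = ("clustering", "local_efficiency", "path_length", "degree", "betweenness")


@dataclass
class FeatureSet:
    """One analysis block: residualized participants x variables matrix plus
    per-variable metadata (metric class, region, hemisphere)."""

    block: str  # games | structure | functional_connectivity | structural_connectivity
    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.columns.equals(self.metadata.index):
            raise ValueError("metadata must cover every data column, in order")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def confound_columns(block: str, mode: str = "base") -> tuple[str, ...]:
    """Confound names for a block. ``mode='extended'`` strictly augments the
    base set with education, income, IQ and go/no-go false alarms."""
    if mode not in ("base", "extended"):
        raise ValueError("confound mode must be 'base' or 'extended'")
    base = BASE_CONFOUNDS if block == "games" else BRAIN_CONFOUNDS
    return base + EXTENDED_EXTRA if mode == "extended" else base


def residualize(table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each column by its OLS residual on [intercept, confounds].

    Residuals are exactly orthogonal to every confound and have mean zero.
    """
    if not table.index.equals(covariates.index):
        raise ValueError("table and covariates must share the participant index")
    if table.isna().any().any() or covariates.isna().any().any():
        raise ValueError("missing values are not allowed (complete-case analysis)")
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confound matrix is rank-deficient after adding an intercept")
    Y = table.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=table.index, columns=table.columns)


def _hemisphere(label: str) -> str:
    if label.startswith(("L_", "Left-")):
        return "L"
    if label.startswith(("R_", "Right-")):
        return "R"
    return "midline"


def connectivity_features(
    study: SyntheticStudy,
    modality: str,
    *,
    max_candidates: int = 20,
    n_sources: int | None = 60,
    use_absolute: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant nodal graph measures + homotopic values for one
    modality. Returns (features, metadata).

    Functional matrices are used as-is (diagonal zeroed for graph analysis);
    structural counts are waytotal-normalized and symmetrized first. Isolated
    nodes' path lengths (no reachable target) are recorded as the
    participant's largest finite path length; the flag counts are kept in
    the metadata attrs.
    """
    if modality not in ("functional", "structural"):
        raise ValueError("modality must be 'functional' or 'structural'")
    tag = "f" if modality == "functional" else "s"
    labels = study.node_labels
    n_nodes = len(labels)
    n = study.n_participants
    parcels = [lb[2:] for lb in labels if lb.startswith("L_")]

    nodal = {m: np.empty((n, n_nodes)) for m in GRAPH_MEASURES}
    inter = np.empty((n, len(parcels)))
    n_flagged = 0
    for i in range(n):
        if modality == "functional":
            w = study.functional[i].astype(float)
        else:
            w = connectome.normalize_tractography(
                study.structural_counts[i], study.waytotal[i]
            )
        np.fill_diagonal(w, 0.0)
        inter[i] = connectome.interhemispheric(w, labels).to_numpy()
        m = connectome.nodal_metrics(
            w, use_absolute=use_absolute,
            max_candidates=max_candidates, n_sources=n_sources,
        )
        L = m.path_length
        if np.isnan(L).any():
            n_flagged += int(np.isnan(L).sum())
            L = np.where(np.isnan(L), np.nanmax(L), L)
        nodal["clustering"][i] = m.clustering
        nodal["local_efficiency"][i] = m.local_efficiency
        nodal["path_length"][i] = L
        nodal["degree"][i] = m.degree
        nodal["betweenness"][i] = m.betweenness

    cols, meta_rows, arrays = [], [], []
    for measure in GRAPH_MEASURES:
        for k, lb in enumerate(labels):
            cols.append(f"{measure}_{tag}_{lb}")
            meta_rows.append((f"{measure}_{tag}", lb[2:], _hemisphere(lb)))
        arrays.append(nodal[measure])
    for k, p in enumerate(parcels):
        cols.append(f"interhemispheric_{tag}_{p}")
        meta_rows.append((f"interhemispheric_{tag}", p, "both"))
    arrays.append(inter)
    feats = pd.DataFrame(np.concatenate(arrays, axis=1),
                         index=study.behavioral.index, columns=cols)
    meta = pd.DataFrame(meta_rows, index=pd.Index(cols, name="column"),
                        columns=["metric_class", "region", "hemisphere"])
    meta.attrs["n_isolated_flagged"] = n_flagged
    return feats, meta


def structure_metadata(columns: list[str]) -> pd.DataFrame:
    rows = []
    for c in columns:
        metric, _, label = c.partition("_")
        if metric == "volume":
            cls = "subcortical_volume"
        elif metric in CORTICAL_METRICS:
            cls = metric
        else:
            raise ValueError(f"unrecognized structure column {c!r}")
        rows.append((cls, label, _hemisphere(label)))
    return pd.DataFrame(rows, index=pd.Index(columns, name="column"),
                        columns=["metric_class", "region", "hemisphere"])


def assemble_brain_blocks(
    structure: pd.DataFrame,
    fc_features: pd.DataFrame,
    fc_meta: pd.DataFrame,
    sc_features: pd.DataFrame,
    sc_meta: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    confounds: str = "base",
) -> dict[str, FeatureSet]:
    """Residualize and package the three brain blocks. All inputs must be
    present — a missing modality is an error, never a silent drop."""
    for name, obj in (("structure", structure), ("functional", fc_features),
                      ("structural", sc_features)):
        if obj is None or len(obj) == 0:
            raise ValueError(f"{name} block input is missing or empty")
    conf = covariates[list(confound_columns("structure", confounds))]
    blocks = {}
    for block, feats, meta in (
        ("structure", structure, structure_metadata(list(structure.columns))),
        ("functional_connectivity", fc_features, fc_meta),
        ("structural_connectivity", sc_features, sc_meta),
    ):
        blocks[block] = FeatureSet(block, residualize(feats, conf), meta)
    return blocks


def build_feature_sets(
    study: SyntheticStudy,
    *,
    confounds: str = "base",
    max_candidates: int = 20,
    n_sources: int | None = 60,
    use_absolute: bool = True,
) -> dict[str, FeatureSet]:
    """Full assembly from a synthetic study: games + structure + functional +
    structural connectivity blocks, each confound-residualized."""
    fc, fc_meta = connectivity_features(
        study, "functional", max_candidates=max_candidates,
        n_sources=n_sources, use_absolute=use_absolute)
    sc, sc_meta = connectivity_features(
        study, "structural", max_candidates=max_candidates,
        n_sources=n_sources, use_absolute=use_absolute)
    brain = assemble_brain_blocks(
        study.structure, fc, fc_meta, sc, sc_meta, study.covariates,
        confounds=confounds)
    games_conf = study.covariates[list(confound_columns("games", confounds))]
    games_meta = pd.DataFrame(
        {
            "metric_class": "game",
            "region": [v.game for v in study.schema],
            "hemisphere": "",
            "direction": [v.direction for v in study.schema],
        },
        index=pd.Index([v.name for v in study.schema], name="column"),
    )
    blocks = {"games": FeatureSet("games", residualize(study.behavioral, games_conf),
                                  games_meta)}
    blocks.update(brain)
    return blocks
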