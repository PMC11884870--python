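"""Permutation significance test for the fitted SMCCA association.

Each null replicate independently shuffles the participant rows of every
brain set while holding the games set fixed (equivalent, under
exchangeability, to shuffling all sets), refits the SMCCA with the
penalties fixed at their observed-data selection, and records the sum of
pairwise canonical correlations. Two p-values are reported: the plain
proportion #{null >= observed}/n_perm and the add-one variant
(#{null >= observed} + 1)/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smcca import SparseMCCA

__all__ = ["PermutationResult", "permutation_test"]


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float  # #{perm >= obs} / n_perm
    p_value_add_one: float  # (#{perm >= obs} + 1) / (n_perm + 1)
    n_perm: int
    seed: int | None

    def summary(self) -> str:
        return (
            f"observed sum of canonical correlations: {self.observed:.4f}\n"
            f"null mean +/- sd: {self.permuted.mean():.4f} +/- "
            f"{self.permuted.std(ddof=1):.4f}  (n_perm={self.n_perm})\n"
            f"p = {self.p_value:.4g}  (add-one: {self.p_value_add_one:.4g})"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"permuted_sum_cor": self.permuted})


def permutation_test(
    sets: dict[str, pd.DataFrame | np.ndarray],
    penalty_fractions: float | list[float],
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    permute_reference: bool = False,
    reselect_grid: list[float] | None = None,
    **model_kw,
) -> PermutationResult:
    """Permutation test of the sum of canonical correlations.

    ``penalty_fractions`` must already be selected on the observed data;
    they stay fixed during the null refits (two-stage procedure). Pass
    ``permute_reference=True`` to also shuffle the first (reference) set,
    or ``reselect_grid`` to re-run penalty selection inside every replicate
    (sensitivity analysis; much slower).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    model = SparseMCCA(sets, penalty_fractions=penalty_fractions, **model_kw)
    observed = model.fit().sum_cor
    rng = np.random.default_rng(seed)
    K = len(model.Zs)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        perms: list[np.ndarray | None] = [
            rng.permutation(model.n) if (i > 0 or permute_reference) else None
            for i in range(K)
        ]
        if reselect_grid is not None:
            from .smcca import select_penalties

            shuffled = {
                name: (Z if p is None else Z[p])
                for (name, Z), p in zip(zip(model.set_names, model.Zs), perms)
            }
            sel = select_penalties(shuffled, reselect_grid, n_perm=50,
                                   seed=rng.integers(2**31))
            model.penalty_fractions = [sel.fraction] * K
            permuted[b] = model._fit_permuted(perms)
            model.penalty_fractions = (
                [penalty_fractions] * K if np.isscalar(penalty_fractions)
                else list(penalty_fractions)
            )
        else:
            permuted[b] = model._fit_permuted(perms)
    n_ge = int((permuted >= observed).sum())
    return PermutationResult(
        observed=observed,
        permuted=permuted,
        p_value=n_ge / n_perm,
        p_value_add_one=(n_ge + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )
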