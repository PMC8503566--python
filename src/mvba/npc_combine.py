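"""Multimodal non-parametric combination (NPC) with the Stouffer function.

Each modality is analyzed with the *same* permutation scheme (synchronized
permutations), its statistic tensor is converted per voxel to empirical
p-value analogs (u-values) by rank within the permutation distribution, and
the per-modality u-values of each permutation are combined voxel-wise with
the Stouffer combining function

    T = sum_k Phi^-1(1 - u_k) / sqrt(K).

Because u-values are rank-based, the combined statistic is invariant to any
strictly monotone transform of the per-modality statistics.  The combined
maps then go through the same TFCE + max-statistic FWER machinery as the
univariate analyses.  GMC is excluded: it has no consistent direction of
change, and NPC as used here looks for concordant decreases after FLAIR and
MD are sign-flipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .perm_stats import (
    FindingsMask,
    PermutationScheme,
    StatTensor,
    TfceParams,
    tfce_fwer_findings,
    perm_t_tensor,
)
from .volume_io import BinaryMask

__all__ = ["NpcParams", "compute_u_values", "stouffer_combine", "run_npc"]


@dataclass
class NpcParams:
    """Combination settings: modalities to combine and the combining function.

    Only the Stouffer function is implemented; the ``combining`` field is a
    config hook.  The upper u clamp 1 - 1/(2 n_perms) keeps the normal
    quantile finite without changing any ordering.
    """

    modalities: tuple[str, ...] = ("FLAIR", "FA", "MD", "NDI")
    combining: str = "stouffer"
    flip_modalities: frozenset = frozenset({"FLAIR", "MD"})

    def __post_init__(self) -> None:
        if len(self.modalities) < 1:
            raise ValueError("NPC requires at least one modality")
        if "GMC" in self.modalities:
            raise ValueError(
                "GMC is excluded from the multimodal analysis (no consistent "
                "direction of change)")
        if self.combining != "stouffer":
            raise ValueError(
                f"unsupported combining function {self.combining!r}; "
                "only 'stouffer' is implemented")


def compute_u_values(tensor: StatTensor) -> np.ndarray:
    """Empirical p-value analogs per permutation and voxel.

    u[j][v] = #{i : T[i][v] >= T[j][v]} / n_perms (self-inclusive, ties
    counted in >=), computed via per-voxel ranks in O(P log P); per voxel
    the largest statistic gets u = 1/n_perms and the smallest u = 1.
    """
    values = tensor.values if isinstance(tensor, StatTensor) else np.asarray(tensor)
    n_perms = values.shape[0]
    # rank 1 = smallest; with method='min' ties share the lowest rank, so
    # count(>=) = n - rank_min + 1 exactly reproduces self-inclusive counting.
    ranks = stats.rankdata(values, method="min", axis=0)
    return (n_perms - ranks + 1) / n_perms


def stouffer_combine(u_by_modality: np.ndarray,
                     u_max: float | None = None) -> np.ndarray:
    """Stouffer combination of K partial-test u-values.

    ``u_by_modality`` stacks modalities on axis 0.  Each u must lie in
    (0, 1]; values are clamped to at most ``u_max`` (typically
    1 - 1/(2 n_perms)) before the normal-quantile transform so the result
    stays finite.  Returns sum_k Phi^-1(1 - u_k) / sqrt(K).
    """
    u = np.asarray(u_by_modality, dtype=np.float64)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("u-values must lie in (0, 1]")
    if u_max is not None:
        u = np.minimum(u, u_max)
    k = u.shape[0]
    z = stats.norm.isf(u)  # Phi^-1(1 - u)
    return z.sum(axis=0) / np.sqrt(k)


def run_npc(
    patient: dict[str, np.ndarray],
    controls: dict[str, np.ndarray],
    mask: BinaryMask,
    scheme: PermutationScheme | None = None,
    tfce_params: TfceParams | None = None,
    npc_params: NpcParams | None = None,
    alpha: float = 0.05,
) -> FindingsMask:
    """Joint multimodal analysis over synchronized permutations.

    For every modality in ``npc_params.modalities`` the same permutation
    scheme produces a statistic tensor oriented so abnormality means a
    decrease (FLAIR/MD are flipped); tensors become u-values, permutations
    are combined voxel-wise with Stouffer, and the combined maps get TFCE
    and max-statistic FWER correction, thresholded at ``alpha``.

    Control stacks must list subjects in the same order in every modality —
    a mismatch in subject count breaks synchronization and is a hard error.
    """
    if npc_params is None:
        npc_params = NpcParams()
    if tfce_params is None:
        tfce_params = TfceParams()
    missing = [m for m in npc_params.modalities if m not in controls or m not in patient]
    if missing:
        raise ValueError(f"missing modality stacks for NPC: {missing}")
    n_subjects = {m: controls[m].shape[0] for m in npc_params.modalities}
    if len(set(n_subjects.values())) != 1:
        raise ValueError(
            f"control counts differ across modalities ({n_subjects}); "
            "synchronized permutations require identical subject order")
    n_controls = next(iter(n_subjects.values()))
    if scheme is None:
        from .perm_stats import build_permutation_scheme
        scheme = build_permutation_scheme(n_controls)
    n_perms = scheme.n_perms
    u_max = 1.0 - 1.0 / (2.0 * n_perms)

    combined = None
    # accumulate in sorted order so the (mathematically symmetric) sum is
    # also bitwise independent of the configured modality order
    for modality in sorted(npc_params.modalities):
        subjects = np.concatenate(
            [controls[modality], np.asarray(patient[modality])[None]], axis=0)
        # decrease test on data oriented so an abnormality is a decrease:
        # the two negations cancel for flipped modalities.
        sign = 1.0 if modality in npc_params.flip_modalities else -1.0
        tensor = perm_t_tensor(sign * subjects, scheme, mask,
                               modality=modality, direction="decrease")
        u = compute_u_values(tensor)
        z = stats.norm.isf(np.minimum(u, u_max))
        combined = z if combined is None else combined + z
    combined /= np.sqrt(len(npc_params.modalities))

    tensor = StatTensor(values=combined, mask=mask, modality="NPC",
                        direction="decrease")
    result = tfce_fwer_findings(tensor, scheme, tfce_params, alpha,
                                 extra_log={
                                     "analysis": "npc",
                                     "combining": npc_params.combining,
                                     "modalities": list(npc_params.modalities),
                                     "u_clamp": u_max,
                                 })
    return result
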