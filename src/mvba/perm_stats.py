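"""Univariate single-case permutation inference with TFCE and FWER control.

The design is a bare two-group contrast with one subject in the "patient"
group and N controls.  The test statistic is the pooled-variance two-sample
t with group sizes (1, N),

    t = (x_patient - mean_controls) / (sd_controls * sqrt(1 + 1/N)),

whose permutation distribution under exchangeability is generated by letting
each of the N+1 subjects take the patient role in turn: a 1-vs-N design has
exactly N+1 distinct relabelings, so the scheme enumerates all of them when
possible (an exact test) and otherwise samples assignments without
replacement.  Statistic maps are enhanced with threshold-free cluster
enhancement (TFCE) and family-wise error is controlled by the permutation
distribution of the map maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask

__all__ = [
    "TfceParams",
    "PermutationScheme",
    "StatTensor",
    "FindingsMask",
    "single_case_t",
    "build_permutation_scheme",
    "perm_t_tensor",
    "tfce_transform",
    "max_statistic_distribution",
    "fwer_pmap",
    "tfce_fwer_findings",
    "run_univariate",
]

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class TfceParams:
    """TFCE exponents and discretization.

    Defaults are the standard choice for volumetric data: height exponent
    H = 2, extent exponent E = 0.5, face (6-) connectivity.  The height
    integral is discretized into ``n_steps`` equal steps up to the map
    maximum (dh = max/n_steps).
    """

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    connectivity: int = 6
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.height_exponent < 0 or self.extent_exponent < 0:
            raise ValueError("TFCE exponents must be >= 0")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class PermutationScheme:
    """Ordered patient-role assignments for a 1-vs-N design.

    ``assignments[k]`` is the index of the subject acting as patient in
    permutation k, with subjects 0..N-1 the controls and subject N the true
    patient; ``assignments[0]`` is always the observed labeling.
    """

    assignments: np.ndarray
    n_controls: int
    exhaustive: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.intp)
        if self.assignments[0] != self.n_controls:
            raise ValueError("assignments[0] must be the observed labeling")
        if self.exhaustive and len(set(self.assignments.tolist())) != len(self.assignments):
            raise ValueError("exhaustive scheme contains duplicate assignments")

    @property
    def n_perms(self) -> int:
        return len(self.assignments)


@dataclass
class StatTensor:
    """Permutation-by-voxel statistic values for the in-mask voxels.

    Row 0 is the observed statistic map.  ``mask`` fixes the embedding of
    the flat voxel axis back into the 3-D grid.
    """

    values: np.ndarray  # (n_perms, n_voxels_in_mask)
    mask: BinaryMask
    modality: str = ""
    direction: str = ""
    n_degenerate: int = 0

    def to_map(self, row: int = 0) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask.data] = self.values[row]
        return out


@dataclass
class FindingsMask:
    """Thresholded result of one analysis: findings plus corrected p-map."""

    findings: BinaryMask
    p_map: np.ndarray          # 3-D corrected p-values (1.0 outside mask)
    observed_tfce: np.ndarray  # 3-D TFCE of the observed map
    null_max: np.ndarray       # per-permutation max TFCE (row 0 observed)
    log: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def single_case_t(patient_values: np.ndarray,
                  control_values: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t with group sizes (1, N), vectorized.

    ``control_values`` has subjects on axis 0.  Voxels where the control
    variance is not positive (constant data, typically a masking artifact)
    get t = 0; their count is logged.
    """
    controls = np.asarray(control_values, dtype=np.float64)
    patient = np.asarray(patient_values, dtype=np.float64)
    n = controls.shape[0]
    if n < 2:
        raise ValueError("at least 2 controls are required")
    mean_c = controls.mean(axis=0)
    sd_c = controls.std(axis=0, ddof=1)
    denom = sd_c * np.sqrt(1.0 + 1.0 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (patient - mean_c) / denom
    bad = ~(sd_c > 0)
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        logger.info("single_case_t: %d zero-variance voxels set to t=0", n_bad)
        t = np.where(bad, 0.0, t)
    return t


def build_permutation_scheme(n_controls: int, requested: int = 10000,
                             seed: int | None = None) -> PermutationScheme:
    """All (or a seeded sample of) patient-role relabelings.

    The label-exchange group of a 1-vs-N design has exactly N+1 distinct
    assignments.  If that many fit within ``requested`` the scheme is
    exhaustive (exact test); otherwise ``requested`` assignments are sampled
    without replacement, always keeping the identity first.
    """
    if n_controls < 2:
        raise ValueError("at least 2 controls are required")
    if requested < 1:
        raise ValueError("requested must be >= 1")
    total = n_controls + 1
    identity = n_controls
    if total <= requested:
        assignments = np.concatenate([[identity], np.arange(n_controls)])
        return PermutationScheme(assignments, n_controls, exhaustive=True,
                                 seed=seed)
    rng = np.random.default_rng(seed)
    others = rng.choice(n_controls, size=requested - 1, replace=False)
    assignments = np.concatenate([[identity], others])
    return PermutationScheme(assignments, n_controls, exhaustive=False,
                             seed=seed)


def perm_t_tensor(subjects: np.ndarray, scheme: PermutationScheme,
                  mask: BinaryMask | None = None,
                  modality: str = "", direction: str = "") -> StatTensor:
    """Single-case t maps for every assignment of a scheme.

    ``subjects`` stacks all N+1 subjects on axis 0 (controls 0..N-1, patient
    last), either flat (S, V) or volumetric (S, nx, ny, nz) with ``mask``.
    For each assignment the designated subject is the patient and the rest
    form the control group; the computation reuses leave-one-out sums, so
    the whole tensor costs barely more than one t map.
    """
    X = np.asarray(subjects, dtype=np.float64)
    if X.ndim == 4:
        if mask is None:
            raise ValueError("mask is required for volumetric input")
        X = X[:, mask.data]
    elif mask is None:
        mask = BinaryMask(np.ones((X.shape[1], 1, 1), dtype=bool))
    s_total = X.shape[0]
    n = s_total - 1  # controls per assignment
    if n < 2:
        raise ValueError("at least 2 controls are required")
    X = X - X.mean(axis=0)  # common shift; t is invariant, improves conditioning
    tot = X.sum(axis=0)
    ssq = (X * X).sum(axis=0)
    a = scheme.assignments
    Xa = X[a]                                   # (P, V) pseudo-patients
    sum_c = tot[None, :] - Xa
    mean_c = sum_c / n
    var_c = (ssq[None, :] - Xa * Xa - sum_c * sum_c / n) / (n - 1)
    denom = np.sqrt(np.clip(var_c, 0.0, None)) * np.sqrt(1.0 + 1.0 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (Xa - mean_c) / denom
    bad = ~(denom > 0)
    n_degenerate = int(np.count_nonzero(bad[0]))
    if bad.any():
        values = np.where(bad, 0.0, values)
    if n_degenerate:
        logger.info("perm_t_tensor: %d zero-variance voxels in observed row",
                    n_degenerate)
    return StatTensor(values=values, mask=mask, modality=modality,
                      direction=direction, n_degenerate=n_degenerate)


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def tfce_transform(stat_map: np.ndarray, mask: BinaryMask,
                   params: TfceParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a one-tailed statistic map.

    For each voxel v,  TFCE(v) = sum over heights h of e(v,h)^E * h^H * dh,
    where e(v,h) is the voxel count of the connected component containing v
    in the excursion set {stat >= h}, and heights run dh, 2dh, ..., max with
    dh = max/n_steps.  Negative values are clamped to 0 first (one-tailed
    orientation); an all-zero map maps to an all-zero map.
    """
    if params is None:
        params = TfceParams()
    stat = np.asarray(stat_map, dtype=np.float64)
    if not np.isfinite(stat).all():
        raise ValueError("non-finite values in statistic map")
    stat = np.where(mask.data, np.clip(stat, 0.0, None), 0.0)
    vmax = stat.max()
    out = np.zeros_like(stat)
    if vmax <= 0:
        return out
    dh = vmax / params.n_steps
    structure = _STRUCTURES[params.connectivity]
    e_exp = params.extent_exponent
    h_exp = params.height_exponent
    for i in range(1, params.n_steps + 1):
        h = i * dh
        labels, n_comp = ndimage.label(stat >= h, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labels.ravel()).astype(np.float64)
        incr = sizes ** e_exp * (h ** h_exp * dh)
        incr[0] = 0.0
        out += incr[labels]
    return out


def max_statistic_distribution(tfce_rows: np.ndarray,
                               mask: BinaryMask | None = None) -> np.ndarray:
    """Per-permutation maximum of enhanced statistics within the mask."""
    rows = np.asarray(tfce_rows, dtype=np.float64)
    if rows.ndim == 2:
        return rows.max(axis=1)
    if mask is None:
        raise ValueError("mask required for volumetric rows")
    return rows[:, mask.data].max(axis=1)


def fwer_pmap(observed_tfce: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    """FWER-corrected p-values from the max-statistic distribution.

    p(v) = #{perms j : null_max[j] >= observed(v)} / n_perms, with ties
    counted against rejection and the identity permutation included, so
    p >= 1/n_perms always.
    """
    null_max = np.asarray(null_max, dtype=np.float64)
    if null_max.size == 0:
        raise ValueError("empty null distribution")
    obs = np.asarray(observed_tfce, dtype=np.float64)
    srt = np.sort(null_max)
    counts = null_max.size - np.searchsorted(srt, obs.ravel(), side="left")
    return (counts / null_max.size).reshape(obs.shape)


# ---------------------------------------------------------------------------
# Full univariate analysis
# ---------------------------------------------------------------------------

def run_univariate(
    patient: np.ndarray,
    controls: np.ndarray,
    mask: BinaryMask,
    direction: str = "decrease",
    scheme: PermutationScheme | None = None,
    tfce_params: TfceParams | None = None,
    alpha: float = 0.05,
    modality: str = "",
) -> FindingsMask:
    """One-tailed single-case analysis of one modality.

    Composes the t tensor (sign set by ``direction``: a decrease test
    negates the data so large t means abnormally low), TFCE per permutation,
    the max-statistic null distribution and FWER-corrected p-values,
    thresholded at ``alpha`` (strict).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    if tfce_params is None:
        tfce_params = TfceParams()
    controls = np.asarray(controls, dtype=np.float64)
    if scheme is None:
        scheme = build_permutation_scheme(controls.shape[0])
    sign = -1.0 if direction == "decrease" else 1.0
    subjects = np.concatenate([controls, np.asarray(patient)[None]], axis=0)
    tensor = perm_t_tensor(sign * subjects, scheme, mask,
                           modality=modality, direction=direction)
    return tfce_fwer_findings(tensor, scheme, tfce_params, alpha,
                               extra_log={"modality": modality,
                                          "direction": direction})


def tfce_fwer_findings(tensor: StatTensor, scheme: PermutationScheme,
                        tfce_params: TfceParams, alpha: float,
                        extra_log: dict | None = None) -> FindingsMask:
    """TFCE + max-statistic FWER on a complete permutation tensor."""
    mask = tensor.mask
    null_max = np.empty(tensor.values.shape[0])
    observed_tfce = None
    for j in range(tensor.values.shape[0]):
        enhanced = tfce_transform(tensor.to_map(j), mask, tfce_params)
        null_max[j] = enhanced[mask.data].max() if mask.data.any() else 0.0
        if j == 0:
            observed_tfce = enhanced
    p_in = fwer_pmap(observed_tfce[mask.data], null_max)
    p_map = np.ones(mask.shape)
    p_map[mask.data] = p_in
    findings = np.zeros(mask.shape, dtype=bool)
    findings[mask.data] = p_in < alpha
    log = {
        "n_perms": scheme.n_perms,
        "exhaustive": bool(scheme.exhaustive),
        "n_degenerate_voxels": tensor.n_degenerate,
        "alpha": alpha,
        "tfce": {"H": tfce_params.height_exponent,
                 "E": tfce_params.extent_exponent,
                 "connectivity": tfce_params.connectivity,
                 "n_steps": tfce_params.n_steps},
    }
    if extra_log:
        log.update(extra_log)
    return FindingsMask(findings=BinaryMask(findings), p_map=p_map,
                        observed_tfce=observed_tfce, null_max=null_max,
                        log=log)
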