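"""Synthetic multi-dataset whole-blood cohort generator with known truth.

Real whole-blood expression is a mixture over hematopoietic cell types.
This module generates such mixtures in the forward direction of the
linear mixing model: a healthy basis ``B`` (genes x cell types), true
per-sample frequency columns ``F`` drawn from a Dirichlet, and observed
expression ``X = B.F`` perturbed by multiplicative log-normal noise and
a dataset-level gene-wise batch factor.  Disease is injected through two
distinct mechanisms, mirroring the two signal classes the downstream
pipeline is designed to separate:

* a *cell-frequency shift* (Dirichlet concentration re-weighting), e.g.
  the myeloid-up / lymphoid-down pattern shared across many diseases;
* *cell-type-restricted differential expression*: selected basis
  entries are scaled by a fold in case samples only.

Every draw is seeded; identical arguments and seed give bit-identical
output.  The generator returns the ground truth (basis, frequencies,
perturbed gene/cell-type pairs) alongside each dataset so recovery can
be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    BasisMatrix,
    CellFrequencyMatrix,
    ExpressionDataset,
    MarkerSets,
    ValidationError,
    make_annotations,
)

# floor on re-weighted Dirichlet concentrations: keeps them positive
ALPHA_FLOOR = 0.01


@dataclass
class DiseaseSpec:
    """Disease definition: frequency shift plus cell-type-restricted DE.

    ``freq_shift`` maps cell types to additive re-weights on the
    Dirichlet concentration (alpha_k <- alpha_k * (1 + shift_k), floored
    at 0.01), so case frequency columns stay on the simplex without
    clipping.  ``de_effects`` lists (cell_type, gene, fold) triples; the
    fold multiplies the basis entry for case samples only (fold > 1 up,
    0 < fold < 1 down).
    """

    name: str
    freq_shift: dict[str, float] = field(default_factory=dict)
    de_effects: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cell_type, gene, fold in self.de_effects:
            if not fold > 0:
                raise ValidationError(
                    f"fold must be > 0 for ({cell_type}, {gene}): {fold}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated dataset."""

    basis: BasisMatrix
    disease_basis: BasisMatrix | None
    frequencies: CellFrequencyMatrix
    de_gene_flags: set[tuple[str, str]]  # (gene, cell_type) truly perturbed


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_basis(
    n_genes: int,
    cell_types: list[str],
    markers_per_type: int,
    marker_fold: float,
    seed,
    meanlog: float = 3.0,
    sdlog: float = 0.5,
    pure_markers: bool = True,
) -> tuple[BasisMatrix, MarkerSets]:
    """Draw a healthy basis matrix and matching marker sets.

    Background entries are log-normal on the linear scale.  Marker genes
    are drawn disjointly across cell types; each marker row is made to
    peak in its own cell type by setting that entry to ``marker_fold``
    times the row's largest background entry (so the row maximum is
    guaranteed).  With ``pure_markers`` the off-type entries of marker
    rows are zeroed, emulating strictly cell-type-exclusive markers.
    """
    if marker_fold <= 1:
        raise ValidationError("marker_fold must be > 1")
    n_markers = markers_per_type * len(cell_types)
    if n_markers > n_genes:
        raise ValidationError(
            f"need {n_markers} marker genes but only {n_genes} genes"
        )
    rng = _rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    values = rng.lognormal(mean=meanlog, sigma=sdlog, size=(n_genes, len(cell_types)))
    marker_idx = rng.choice(n_genes, size=n_markers, replace=False)
    sets: dict[str, list[str]] = {}
    for k, cell_type in enumerate(cell_types):
        idx = marker_idx[k * markers_per_type : (k + 1) * markers_per_type]
        sets[cell_type] = [genes[i] for i in idx]
        for i in idx:
            peak = marker_fold * values[i].max()
            if pure_markers:
                values[i, :] = 0.0
            values[i, k] = peak
    basis = BasisMatrix(pd.DataFrame(values, index=genes, columns=list(cell_types)))
    return basis, MarkerSets(sets)


def _shifted_alpha(alpha: np.ndarray, cell_types, freq_shift) -> np.ndarray:
    shifted = alpha.copy()
    for k, ct in enumerate(cell_types):
        shifted[k] = max(alpha[k] * (1.0 + freq_shift.get(ct, 0.0)), ALPHA_FLOOR)
    return shifted


def apply_de_effects(basis: BasisMatrix, spec: DiseaseSpec) -> BasisMatrix:
    """Return the disease-condition basis B' with fold changes applied."""
    values = basis.values.copy()
    for cell_type, gene, fold in spec.de_effects:
        values.loc[gene, cell_type] *= fold
    return BasisMatrix(values)


def simulate_dataset(
    basis: BasisMatrix,
    spec: DiseaseSpec | None,
    n_case: int,
    n_control: int,
    dirichlet_alpha,
    noise_cv: float = 0.0,
    batch_scale_sd: float = 0.0,
    seed=0,
    dataset_id: str = "ds1",
    fixed_frequencies=None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate one case/control dataset from the mixing model.

    Per sample a frequency column is drawn from Dirichlet(alpha) (cases:
    alpha re-weighted by the disease's ``freq_shift``); case columns mix
    through the disease basis, control columns through the healthy one.
    Entries are multiplied by unit-mean log-normal noise with coefficient
    of variation ``noise_cv`` and by one gene-wise batch factor
    ``exp(N(0, batch_scale_sd^2))`` shared by all samples of the dataset.

    ``fixed_frequencies`` (one column per sample or a single vector)
    bypasses the Dirichlet draw, for deterministic mixing checks.
    """
    if n_case < 0 or n_control < 0:
        raise ValidationError("sample counts must be >= 0")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValidationError("dirichlet_alpha must be positive")
    cell_types = basis.cell_types
    if alpha.shape != (len(cell_types),):
        raise ValidationError("alpha length must match cell types")
    rng = _rng(seed)
    n = n_case + n_control

    if fixed_frequencies is not None:
        fixed = np.asarray(fixed_frequencies, dtype=float)
        if fixed.ndim == 1:
            fixed = np.tile(fixed[:, None], (1, n))
        F = fixed.copy()
    else:
        case_alpha = alpha
        if spec is not None:
            case_alpha = _shifted_alpha(alpha, cell_types, spec.freq_shift)
        f_case = (
            rng.dirichlet(case_alpha, size=n_case).T
            if n_case
            else np.zeros((len(cell_types), 0))
        )
        f_ctrl = (
            rng.dirichlet(alpha, size=n_control).T
            if n_control
            else np.zeros((len(cell_types), 0))
        )
        F = np.concatenate([f_case, f_ctrl], axis=1)
    F = F / F.sum(axis=0, keepdims=True)

    disease_basis = apply_de_effects(basis, spec) if spec is not None else None
    b_healthy = basis.values.to_numpy()
    b_case = disease_basis.values.to_numpy() if disease_basis is not None else b_healthy
    X = np.empty((b_healthy.shape[0], n))
    if n_case:
        X[:, :n_case] = b_case @ F[:, :n_case]
    if n_control:
        X[:, n_case:] = b_healthy @ F[:, n_case:]

    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=X.shape)
        X = X * noise
    if batch_scale_sd > 0:
        batch = np.exp(rng.normal(0.0, batch_scale_sd, size=X.shape[0]))
        X = X * batch[:, None]

    sample_ids = [f"{dataset_id}.s{i:03d}" for i in range(n)]
    groups = ["case"] * n_case + ["control"] * n_control
    disease = spec.name if spec is not None else None
    diseases = [disease] * n_case + [None] * n_control
    ann = make_annotations(sample_ids, dataset_id, groups, diseases)
    ds = ExpressionDataset(
        pd.DataFrame(X, index=basis.gene_ids, columns=sample_ids),
        scale="linear",
        annotations=ann,
    )
    truth = SyntheticTruth(
        basis=basis,
        disease_basis=disease_basis,
        frequencies=CellFrequencyMatrix(
            pd.DataFrame(F, index=cell_types, columns=sample_ids)
        ),
        de_gene_flags=(
            {(g, ct) for ct, g, _ in spec.de_effects} if spec is not None else set()
        ),
    )
    return ds, truth


def simulate_collection(
    specs: list[tuple[DiseaseSpec, int, tuple[int, int]]],
    basis: BasisMatrix,
    dirichlet_alpha,
    shared_shift: dict[str, float] | None = None,
    shared_subset: list[str] | None = None,
    noise_cv: float = 0.2,
    batch_scale_sd: float = 0.3,
    seed=0,
) -> list[tuple[ExpressionDataset, SyntheticTruth]]:
    """Simulate a multi-disease, multi-dataset collection.

    ``specs`` lists (DiseaseSpec, n_datasets, (n_case, n_control)).
    Diseases named in ``shared_subset`` (default: all) receive
    ``shared_shift`` added to their own frequency shift, emulating a
    cell-composition pattern common across diseases.  Each dataset gets
    its own batch seed, so batch factors differ between datasets of the
    same disease.
    """
    shared_shift = shared_shift or {}
    names = [s.name for s, _, _ in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate disease names in collection spec")
    subset = set(shared_subset) if shared_subset is not None else set(names)
    master = _rng(seed)
    out: list[tuple[ExpressionDataset, SyntheticTruth]] = []
    dataset_ids: set[str] = set()
    for spec, n_datasets, (n_case, n_control) in specs:
        shift = dict(spec.freq_shift)
        if spec.name in subset:
            for ct, v in shared_shift.items():
                shift[ct] = shift.get(ct, 0.0) + v
        eff_spec = DiseaseSpec(spec.name, shift, list(spec.de_effects))
        for d in range(n_datasets):
            dataset_id = f"{spec.name}.d{d + 1}"
            if dataset_id in dataset_ids:
                raise ValidationError(f"duplicate dataset id {dataset_id}")
            dataset_ids.add(dataset_id)
            child = int(master.integers(2**31))
            out.append(
                simulate_dataset(
                    basis,
                    eff_spec,
                    n_case,
                    n_control,
                    dirichlet_alpha,
                    noise_cv=noise_cv,
                    batch_scale_sd=batch_scale_sd,
                    seed=child,
                    dataset_id=dataset_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Default benchmark: the standard study conditions used throughout the tests.
# ---------------------------------------------------------------------------

BENCHMARK_CELL_TYPES = ["granulocyte", "monocyte", "CD4_T", "B_cell"]
# low total concentration: whole-blood composition varies strongly between
# individuals (and more so in disease cohorts), and composition is the
# dominant source of between-sample expression variance in whole blood
BENCHMARK_ALPHA = [3.84, 1.28, 1.92, 0.96]
# common myeloid-up / lymphoid-down composition pattern shared by diseases
BENCHMARK_SHARED_SHIFT = {
    "granulocyte": 0.5,
    "monocyte": 0.5,
    "CD4_T": -0.35,
    "B_cell": -0.35,
}
# per-disease composition signatures on top of the shared shift (shifts act
# as concentration multipliers 1+shift, so distinctiveness is relative)
BENCHMARK_OWN_SHIFTS = {
    "diseaseA": {"monocyte": 0.7},
    "diseaseB": {"granulocyte": 0.5, "B_cell": -0.3},
    "diseaseC": {"B_cell": 1.2, "granulocyte": -0.25},
}
# cell type whose molecular state changes in each disease (gene sets are
# disjoint across diseases, so shared cells still carry distinct signatures)
BENCHMARK_DE_CELL = {
    "diseaseA": "monocyte",
    "diseaseB": "granulocyte",
    "diseaseC": "monocyte",
}


def default_benchmark(
    seed,
    n_genes: int = 400,
    markers_per_type: int = 10,
    marker_fold: float = 50.0,
    basis_sdlog: float = 1.2,
    n_datasets_per_disease: int = 2,
    n_case: int = 20,
    n_control: int = 30,
    de_genes_per_disease: int = 25,
    de_fold_up: float = 1.7,
    de_fold_down: float = 0.59,
    noise_cv: float = 0.1,
    batch_scale_sd: float = 0.3,
    shared_shift: dict[str, float] | None = None,
) -> tuple[
    list[tuple[ExpressionDataset, SyntheticTruth]], BasisMatrix, MarkerSets
]:
    """Build the default three-disease benchmark collection.

    Three "diseases" share the myeloid-up / lymphoid-down composition
    shift, carry distinct disease-specific composition signatures, and
    each perturb a disjoint set of genes in one cell type (half up at
    ``de_fold_up``, half down at ``de_fold_down``).  Two datasets per
    disease with independent batch factors.  The basis is strongly
    cell-type specific (``basis_sdlog`` well above the generic default),
    emulating the lineage-restricted expression of real blood genes.
    Returns the collection plus the healthy basis and marker sets.
    """
    rng = np.random.default_rng(seed)
    basis_seed = int(rng.integers(2**31))
    coll_seed = int(rng.integers(2**31))
    basis, markers = make_basis(
        n_genes,
        BENCHMARK_CELL_TYPES,
        markers_per_type,
        marker_fold,
        seed=basis_seed,
        sdlog=basis_sdlog,
    )
    marker_genes = set(markers.all_genes())
    candidates = [g for g in basis.gene_ids if g not in marker_genes]
    picked = rng.choice(
        len(candidates),
        size=de_genes_per_disease * len(BENCHMARK_OWN_SHIFTS),
        replace=False,
    )
    specs = []
    for i, (name, own_shift) in enumerate(BENCHMARK_OWN_SHIFTS.items()):
        idx = picked[i * de_genes_per_disease : (i + 1) * de_genes_per_disease]
        cell_type = BENCHMARK_DE_CELL[name]
        de = [
            (
                cell_type,
                candidates[j],
                de_fold_up if pos % 2 == 0 else de_fold_down,
            )
            for pos, j in enumerate(idx)
        ]
        specs.append(
            (DiseaseSpec(name, own_shift, de), n_datasets_per_disease, (n_case, n_control))
        )
    shared = BENCHMARK_SHARED_SHIFT if shared_shift is None else shared_shift
    collection = simulate_collection(
        specs,
        basis,
        BENCHMARK_ALPHA,
        shared_shift=shared,
        noise_cv=noise_cv,
        batch_scale_sd=batch_scale_sd,
        seed=coll_seed,
    )
    return collection, basis, markers
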