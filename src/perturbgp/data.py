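"""Dataset containers, perturbation encodings, file IO and the train/test split.

A perturbation screen is represented by three aligned matrices:

* ``X`` — N cells x P genes of expression (raw UMI counts for the
  count modality, pre-normalised real values for the continuous modality);
* ``C`` — N x L perturbation design (one-hot for single-guide screens,
  multi-hot for combinatorial screens, a single non-zero real entry for
  dosage screens; an all-zero row marks a non-targeting control cell);
* ``K`` — N x D cell-level covariates (library size, detected genes,
  mitochondrial fraction, batch, ...), fully user-defined.

No normalisation or covariate regression is performed here: the model
disentangles basal and perturbation-driven variation itself, so expression
enters on the scale the user supplies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PerturbDataset",
    "SplitIndices",
    "ValidationError",
    "encode_perturbations",
    "load_dataset",
    "write_dataset",
    "split_train_test",
]


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


def _as_2d(name: str, arr) -> np.ndarray:
    out = np.asarray(arr)
    if out.ndim == 1:
        out = out[:, None]
    if out.ndim != 2:
        raise ValidationError(f"{name} must be 2-dimensional, got shape {out.shape}")
    return out


@dataclass
class PerturbDataset:
    """Aligned (X, C, K) matrices with names and a modality flag.

    Parameters
    ----------
    X
        N x P expression matrix. Non-negative integers when
        ``modality='count'``, real-valued when ``modality='continuous'``.
    C
        N x L non-negative perturbation matrix. All-zero rows are
        non-targeting controls.
    K
        N x D real cell-covariate matrix.
    gene_names, perturbation_names, covariate_names
        Axis labels; identity is carried by name, not position.
    modality
        ``'count'`` or ``'continuous'``.
    """

    X: np.ndarray
    C: np.ndarray
    K: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    perturbation_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)
    modality: str = "continuous"

    def __post_init__(self) -> None:
        self.X = _as_2d("X", self.X).astype(np.float64)
        self.C = _as_2d("C", self.C).astype(np.float64)
        self.K = _as_2d("K", self.K).astype(np.float64)
        if self.modality not in ("count", "continuous"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        n = self.X.shape[0]
        for name, mat in (("C", self.C), ("K", self.K)):
            if mat.shape[0] != n:
                raise ValidationError(
                    f"row mismatch on axis 'cells': X has {n} rows, {name} has {mat.shape[0]}"
                )
        for name, mat in (("X", self.X), ("C", self.C), ("K", self.K)):
            if not np.all(np.isfinite(mat)):
                raise ValidationError(f"{name} contains non-finite values")
        if np.any(self.C < 0):
            raise ValidationError("C must be non-negative")
        if self.modality == "count":
            if np.any(self.X < 0) or not np.allclose(self.X, np.round(self.X)):
                raise ValidationError(
                    "modality='count' requires non-negative integer X entries"
                )
        if not self.gene_names:
            self.gene_names = [f"g{j}" for j in range(self.X.shape[1])]
        if not self.perturbation_names:
            self.perturbation_names = [f"p{j}" for j in range(self.C.shape[1])]
        if not self.covariate_names:
            self.covariate_names = [f"k{j}" for j in range(self.K.shape[1])]
        for label, names, dim in (
            ("gene_names", self.gene_names, self.X.shape[1]),
            ("perturbation_names", self.perturbation_names, self.C.shape[1]),
            ("covariate_names", self.covariate_names, self.K.shape[1]),
        ):
            if len(names) != dim:
                raise ValidationError(
                    f"{label} has {len(names)} entries for axis of size {dim}"
                )

    # -- basic bookkeeping -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def n_perturbation_axes(self) -> int:
        return self.C.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.K.shape[1]

    def is_control(self) -> np.ndarray:
        """Boolean mask of non-targeting control cells (all-zero C rows)."""
        return ~np.any(self.C != 0, axis=1)

    def subset(self, rows: np.ndarray) -> "PerturbDataset":
        rows = np.asarray(rows)
        return PerturbDataset(
            X=self.X[rows],
            C=self.C[rows],
            K=self.K[rows],
            gene_names=list(self.gene_names),
            perturbation_names=list(self.perturbation_names),
            covariate_names=list(self.covariate_names),
            modality=self.modality,
        )


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint, exhaustive train/test row partition, reproducible from seed."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    seed: int


def split_train_test(
    dataset: PerturbDataset | int, test_fraction: float = 0.2, seed: int = 0
) -> SplitIndices:
    """Random row split; ``|test| = round(test_fraction * N)``.

    ``dataset`` may also be the integer N directly.
    """
    n = dataset if isinstance(dataset, (int, np.integer)) else dataset.n_cells
    if n < 2:
        raise ValidationError("need at least 2 rows to split")
    if not (0.0 < test_fraction < 1.0):
        raise ValidationError("test_fraction must lie in (0, 1)")
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 0), n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return SplitIndices(train_rows=train, test_rows=test, seed=int(seed))


def encode_perturbations(
    labels: Sequence,
    mode: str = "onehot",
    control_token: str = "control",
) -> tuple[np.ndarray, list[str]]:
    """Turn per-cell perturbation annotations into the design matrix C.

    Modes
    -----
    onehot
        ``labels`` are strings; each distinct non-control label becomes a
        column; the control token maps to an all-zero row.
    multihot
        ``labels`` are strings with ``+``-joined targets (``"g1+g2"``);
        every listed target gets a 1.
    dosage
        ``labels`` are ``(compound, dose)`` pairs with dose >= 0; the row has
        a single non-zero entry equal to the dose.  The control token (as a
        bare string or as the compound) maps to an all-zero row.
    """
    if mode not in ("onehot", "multihot", "dosage"):
        raise ValidationError(f"unknown encoding mode {mode!r}")

    if mode == "dosage":
        compounds: list[str] = []
        parsed: list[tuple[str, float] | None] = []
        for lab in labels:
            if isinstance(lab, str):
                if lab != control_token:
                    raise ValidationError(
                        f"dosage mode requires (compound, dose) pairs; got bare label {lab!r}"
                    )
                parsed.append(None)
                continue
            compound, dose = lab
            if compound == control_token:
                parsed.append(None)
                continue
            dose = float(dose)
            if dose < 0:
                raise ValidationError(f"negative dose {dose} for compound {compound!r}")
            if compound not in compounds:
                compounds.append(compound)
            parsed.append((compound, dose))
        C = np.zeros((len(parsed), len(compounds)))
        for i, entry in enumerate(parsed):
            if entry is not None:
                C[i, compounds.index(entry[0])] = entry[1]
        return C, compounds

    names: list[str] = []
    rows: list[list[str]] = []
    for lab in labels:
        if lab == control_token:
            rows.append([])
            continue
        targets = lab.split("+") if mode == "multihot" else [lab]
        for t in targets:
            if t not in names:
                names.append(t)
        rows.append(targets)
    C = np.zeros((len(rows), len(names)))
    for i, targets in enumerate(rows):
        for t in targets:
            C[i, names.index(t)] = 1.0
    if mode == "onehot" and np.any(np.count_nonzero(C, axis=1) > 1):
        raise ValidationError("onehot mode saw a multi-target label; use multihot")
    return C, names


# ---------------------------------------------------------------------------
# Readers / writers.  Three routes: AnnData h5ad, MatrixMarket + delimited
# sidecars, plain delimited tables.  All delimited files are comma-separated
# UTF-8 with a header row.
# ---------------------------------------------------------------------------

_MTX_FILES = {
    "matrix": "matrix.mtx",
    "genes": "genes.csv",
    "perturbations": "perturbations.csv",
    "covariates": "covariates.csv",
}
_DELIM_FILES = {
    "expression": "expression.csv",
    "perturbations": "perturbations.csv",
    "covariates": "covariates.csv",
}


def load_dataset(
    path: str | Path,
    format: str = "h5ad",
    modality: str = "continuous",
    field_map: Mapping | None = None,
) -> PerturbDataset:
    """Read a dataset from one of the supported on-disk layouts.

    ``field_map`` names where the perturbation and covariate blocks live:

    * h5ad — ``{"pert_key": obsm key, "covariate_cols": [obs columns],
      "layer": optional layer name}``; perturbation names are looked up in
      ``uns[pert_key + "_names"]`` when present.
    * mtx — directory holding ``matrix.mtx`` (cells x genes), ``genes.csv``,
      ``perturbations.csv`` (N x L, header = perturbation names) and
      ``covariates.csv`` (N x D, header = covariate names).
    * delimited — directory with ``expression.csv`` (header = gene names),
      ``perturbations.csv`` and ``covariates.csv``.
    """
    path = Path(path)
    field_map = dict(field_map or {})
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        layer = field_map.get("layer")
        X = adata.layers[layer] if layer else adata.X
        X = np.asarray(X.toarray() if hasattr(X, "toarray") else X)
        pert_key = field_map.get("pert_key", "perturbation")
        if pert_key not in adata.obsm:
            raise ValidationError(f"obsm key {pert_key!r} not found in {path}")
        C = np.asarray(adata.obsm[pert_key])
        pert_names = list(adata.uns.get(f"{pert_key}_names", []))
        cov_cols = field_map.get("covariate_cols")
        if cov_cols is None:
            cov_cols = [c for c in adata.obs.columns if adata.obs[c].dtype.kind in "fiu"]
        K = adata.obs[list(cov_cols)].to_numpy(dtype=float)
        return PerturbDataset(
            X=X,
            C=C,
            K=K,
            gene_names=list(adata.var_names),
            perturbation_names=[str(p) for p in pert_names],
            covariate_names=[str(c) for c in cov_cols],
            modality=modality,
        )

    if format == "mtx":
        from scipy.io import mmread

        X = np.asarray(mmread(path / _MTX_FILES["matrix"]).todense(), dtype=float)
        genes = pd.read_csv(path / _MTX_FILES["genes"])
        pert = pd.read_csv(path / _MTX_FILES["perturbations"])
        cov = pd.read_csv(path / _MTX_FILES["covariates"])
        return PerturbDataset(
            X=X,
            C=pert.to_numpy(dtype=float),
            K=cov.to_numpy(dtype=float),
            gene_names=[str(g) for g in genes.iloc[:, 0]],
            perturbation_names=[str(c) for c in pert.columns],
            covariate_names=[str(c) for c in cov.columns],
            modality=modality,
        )

    if format == "delimited":
        expr = pd.read_csv(path / _DELIM_FILES["expression"])
        pert = pd.read_csv(path / _DELIM_FILES["perturbations"])
        cov = pd.read_csv(path / _DELIM_FILES["covariates"])
        return PerturbDataset(
            X=expr.to_numpy(dtype=float),
            C=pert.to_numpy(dtype=float),
            K=cov.to_numpy(dtype=float),
            gene_names=[str(c) for c in expr.columns],
            perturbation_names=[str(c) for c in pert.columns],
            covariate_names=[str(c) for c in cov.columns],
            modality=modality,
        )

    raise ValidationError(f"unknown format {format!r}")


def write_dataset(
    dataset: PerturbDataset,
    path: str | Path,
    format: str = "h5ad",
    field_map: Mapping | None = None,
) -> Path:
    """Write a dataset in one of the supported layouts (inverse of load)."""
    path = Path(path)
    field_map = dict(field_map or {})

    if format == "h5ad":
        import anndata as ad

        pert_key = field_map.get("pert_key", "perturbation")
        obs = pd.DataFrame(
            dataset.K,
            columns=dataset.covariate_names,
            index=[f"cell{i}" for i in range(dataset.n_cells)],
        )
        adata = ad.AnnData(X=dataset.X.copy(), obs=obs)
        adata.var_names = dataset.gene_names
        adata.obsm[pert_key] = dataset.C.copy()
        adata.uns[f"{pert_key}_names"] = list(dataset.perturbation_names)
        adata.write_h5ad(path)
        return path

    path.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path / _MTX_FILES["matrix"]), csr_matrix(dataset.X))
        pd.DataFrame({"gene": dataset.gene_names}).to_csv(
            path / _MTX_FILES["genes"], index=False
        )
        pd.DataFrame(dataset.C, columns=dataset.perturbation_names).to_csv(
            path / _MTX_FILES["perturbations"], index=False
        )
        pd.DataFrame(dataset.K, columns=dataset.covariate_names).to_csv(
            path / _MTX_FILES["covariates"], index=False
        )
        return path

    if format == "delimited":
        pd.DataFrame(dataset.X, columns=dataset.gene_names).to_csv(
            path / _DELIM_FILES["expression"], index=False
        )
        pd.DataFrame(dataset.C, columns=dataset.perturbation_names).to_csv(
            path / _DELIM_FILES["perturbations"], index=False
        )
        pd.DataFrame(dataset.K, columns=dataset.covariate_names).to_csv(
            path / _DELIM_FILES["covariates"], index=False
        )
        return path

    raise ValidationError(f"unknown format {format!r}")
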