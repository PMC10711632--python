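"""Probe-level quality control and covariate principal components.

Probe exclusion applies five flag classes sequentially — poor detection
p-value, low beadcount, probes not at a CpG start, probes on a published
mask list, and sex-chromosome probes — so the per-class removal counts are
disjoint and sum, with the retained count, to the input probe number.

Age and blood cell-type fractions are collinear by construction (fractions
sum to one) and correlated with each other, so downstream models adjust for
their leading principal components instead of the raw features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FLAG_COLUMNS, cell_fraction_columns

logger = logging.getLogger(__name__)

__all__ = ["QcReport", "CovariatePCs", "filter_probes", "compute_covariate_pcs"]


@dataclass
class QcReport:
    """Removal counts per exclusion class, in order of application."""

    removed: dict[str, int]
    n_input: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"criterion": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


def filter_probes(
    beta: pd.DataFrame, annot: pd.DataFrame
) -> tuple[pd.DataFrame, QcReport]:
    """Drop every probe with any exclusion flag set.

    Filters run sequentially in the canonical order, so a probe flagged in
    two classes is counted once, under the first matching class. The result
    may be empty; that is reported, not an error.
    """
    missing = beta.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"probes without annotation: {missing.tolist()[:5]}")
    flags = annot.loc[beta.index, FLAG_COLUMNS].astype(bool)
    keep = pd.Series(True, index=beta.index)
    removed: dict[str, int] = {}
    for col in FLAG_COLUMNS:
        hit = keep & flags[col]
        removed[col] = int(hit.sum())
        keep &= ~flags[col]
    filtered = beta.loc[keep]
    report = QcReport(removed=removed, n_input=len(beta), n_retained=len(filtered))
    return filtered, report


@dataclass
class CovariatePCs:
    """Leading principal components of the standardized covariates.

    ``scores`` is subject x component; ``explained_variance`` the fraction
    of total covariate variance per retained component; ``loadings`` the
    feature weights. ``dropped`` lists constant features excluded before
    decomposition.
    """

    scores: pd.DataFrame
    explained_variance: np.ndarray
    loadings: pd.DataFrame
    dropped: list[str] = field(default_factory=list)


def compute_covariate_pcs(
    sheet: pd.DataFrame,
    features: list[str] | None = None,
    *,
    var_explained: float = 0.95,
) -> CovariatePCs:
    """PCA of standardized subject covariates (default: age + cell fractions).

    Retains the smallest number of leading components whose cumulative
    explained variance reaches ``var_explained``. Sign convention: in each
    component the largest-magnitude loading is positive, which makes scores
    deterministic and invariant (up to nothing) to subject order.
    """
    if features is None:
        features = ["age"] + cell_fraction_columns(sheet)
    if len(sheet) < 2:
        raise ValueError("PCA needs at least two subjects")
    X = sheet[features].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0.0
    dropped = [f for f, c in zip(features, constant) if c]
    if dropped:
        logger.warning("compute_covariate_pcs: dropping constant feature(s) %s", dropped)
    kept = [f for f, c in zip(features, constant) if not c]
    if not kept:
        raise ValueError("all covariate features are constant")
    X = X[:, ~constant]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    # SVD of the standardized matrix; scores = U * s, loadings = V
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / np.sum(s**2)
    n_comp = int(np.searchsorted(np.cumsum(var), min(var_explained, 1.0 - 1e-12)) + 1)
    n_comp = min(n_comp, len(s))
    # fix signs so the largest-|loading| entry of each component is positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    names = [f"PC{k + 1}" for k in range(n_comp)]
    scores = pd.DataFrame(U[:, :n_comp] * s[:n_comp], index=sheet.index, columns=names)
    loadings = pd.DataFrame(Vt[:n_comp].T, index=kept, columns=names)
    return CovariatePCs(
        scores=scores,
        explained_variance=var[:n_comp],
        loadings=loadings,
        dropped=dropped,
    )
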