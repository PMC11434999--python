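"""Profile analysis of signal drugs: lnROR matrix, Ward clustering, PCA.

Each signal drug gets a side-effect profile: the Haldane-corrected lnROR
against each retained chemosensory PT (PTs are retained when they reach a
database-wide report-count floor; at full FAERS scale the floor of 3000
keeps the seven frequent terms: dysgeusia, ageusia, taste disorder,
anosmia, parosmia, hypogeusia, hyposmia).  The drug-by-PT matrix feeds
Ward minimum-variance hierarchical clustering and a correlation-matrix
PCA whose leading components separate overall risk, taste-versus-smell,
and decreased-versus-altered perception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .disproportionality import haldane_correct, make_contingency, ror
from .errors import DegenerateDataError
from .faers_model import TableA
from .vocab import SmqTermSet, normalize_term

#: Database-wide report-count floor for a PT column (full-FAERS scale).
DEFAULT_PT_MIN_REPORTS = 3000


@dataclass
class LnRorMatrix:
    """Signal-drug x PT matrix of Haldane-corrected lnROR values."""

    values: pd.DataFrame
    pt_report_counts: pd.Series

    @property
    def drugs(self) -> list[str]:
        return list(self.values.index)

    @property
    def pts(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)


def build_lnror_matrix(
    table_a: TableA,
    drugs: Sequence[str],
    smq: SmqTermSet | None = None,
    pt_min_reports: int = DEFAULT_PT_MIN_REPORTS,
) -> LnRorMatrix:
    """Build the drug-by-PT lnROR profile matrix.

    Columns are the SMQ PTs whose database-wide (all drugs) report count
    reaches ``pt_min_reports``, ordered by descending count; cells are
    lnROR of the (drug, single-PT) table after Haldane correction, so
    every cell is finite.
    """
    if not len(drugs):
        raise ValueError("drugs must be non-empty")
    smq = smq if smq is not None else table_a.smq
    counts = table_a.pt_report_counts()
    counts = counts[counts.index.isin(smq.all_terms)]
    kept = counts[counts >= pt_min_reports]
    if kept.empty:
        raise DegenerateDataError(
            f"no SMQ PT reaches {pt_min_reports} database-wide reports"
        )

    drug_names = [normalize_term(d) for d in drugs]
    n_total = table_a.n_reports
    exposure = {d: table_a.ids_with_drug(d) for d in drug_names}
    cells = np.empty((len(drug_names), len(kept)))
    for j, pt in enumerate(kept.index):
        with_event = table_a.ids_with_any_pt([pt])
        n_event = len(with_event)
        for i, d in enumerate(drug_names):
            exp = exposure[d]
            a = len(exp.intersection(with_event))
            raw = _table(a, len(exp), n_event, n_total)
            _, ln = ror(haldane_correct(raw))
            cells[i, j] = ln
    values = pd.DataFrame(cells, index=drug_names, columns=list(kept.index))
    return LnRorMatrix(values=values, pt_report_counts=kept)


def _table(a: int, n_exposed: int, n_event: int, n_total: int):
    from .disproportionality import ContingencyTable2x2

    return ContingencyTable2x2(a, n_exposed - a, n_event - a,
                               n_total - n_exposed - (n_event - a))


@dataclass
class ClusteringResult:
    """Ward dendrogram plus a flat assignment at k clusters."""

    linkage_matrix: np.ndarray
    assignment: pd.Series  # drug -> cluster id in 1..k
    labels: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return int(self.assignment.nunique())

    def merge_sets(self) -> list[frozenset]:
        """The agglomeration sequence: at each step, the frozenset pair
        {A, B} of leaf-index sets that merged."""
        n = len(self.labels)
        clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        merges = []
        for step, (i, j, _h, _cnt) in enumerate(self.linkage_matrix):
            left, right = clusters.pop(int(i)), clusters.pop(int(j))
            merges.append(frozenset([left, right]))
            clusters[n + step] = left | right
        return merges

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Nested-parenthesis export of the dendrogram with branch lengths."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.labels[i].replace(" ", "_") for i in range(n)}
        for step, (i, j, h, _cnt) in enumerate(self.linkage_matrix):
            i, j = int(i), int(j)
            bl_i, bl_j = h - height[i], h - height[j]
            node[n + step] = f"({node[i]}:{bl_i:.6g},{node[j]}:{bl_j:.6g})"
            height[n + step] = h
        return node[n + len(self.linkage_matrix) - 1] + ";"

    def assignment_frame(self) -> pd.DataFrame:
        return (
            self.assignment.rename("cluster")
            .rename_axis("drug")
            .reset_index()
            .sort_values(["cluster", "drug"])
            .reset_index(drop=True)
        )


def ward_cluster(matrix: LnRorMatrix | pd.DataFrame, k: int) -> ClusteringResult:
    """Agglomerative clustering with Ward's minimum-variance criterion on
    Euclidean distances between drug profiles, cut into k flat clusters.

    At each step the pair of clusters whose merge least increases the
    total within-cluster sum of squares is joined.  Heights are the
    standard Ward linkage distances (non-decreasing along merges).
    """
    df = matrix.values if isinstance(matrix, LnRorMatrix) else matrix
    n = len(df)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and the number of rows ({n})")
    if n == 1:
        return ClusteringResult(
            linkage_matrix=np.empty((0, 4)),
            assignment=pd.Series([1], index=df.index),
            labels=list(df.index),
        )
    Z = linkage(df.to_numpy(dtype=float), method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return ClusteringResult(
        linkage_matrix=Z,
        assignment=pd.Series(flat, index=df.index),
        labels=list(df.index),
    )


@dataclass
class PcaResult:
    """Correlation-matrix PCA: loadings, scores, explained variance."""

    loadings: pd.DataFrame  # PT x component
    scores: pd.DataFrame  # drug x component
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray

    def component(self, number: int) -> pd.Series:
        """Scores of a 1-based component."""
        return self.scores[f"PC{number}"]


def pca(matrix: LnRorMatrix | pd.DataFrame) -> PcaResult:
    """PCA on the column-correlation matrix of the lnROR profiles.

    Columns are standardized (sample sd); components are eigenvectors of
    the correlation matrix ordered by decreasing eigenvalue.  Each
    component is oriented so its largest-magnitude loading is positive
    (the underlying signs are arbitrary).  Explained fractions are
    eigenvalues over their total and sum to 1.
    """
    df = matrix.values if isinstance(matrix, LnRorMatrix) else matrix
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        names = [df.columns[i] for i in degenerate]
        raise DegenerateDataError(f"constant lnROR column(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), V[:, order]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    names = [f"PC{i + 1}" for i in range(len(w))]
    return PcaResult(
        loadings=pd.DataFrame(V, index=df.columns, columns=names),
        scores=pd.DataFrame(Z @ V, index=df.index, columns=names),
        eigenvalues=w,
        explained_fraction=w / w.sum(),
    )


def interpret_components(
    result: PcaResult,
    matrix: LnRorMatrix | pd.DataFrame,
    components: Iterable[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Pearson correlation of component scores against each PT's lnROR
    column, with two-sided p-values.

    The sign/significance table reads off what each component represents:
    e.g. a component correlating positively with taste PTs and negatively
    with smell PTs is a taste-versus-smell contrast.
    """
    df = matrix.values if isinstance(matrix, LnRorMatrix) else matrix
    rows = []
    for comp in components:
        scores = result.component(comp).to_numpy()
        for pt in df.columns:
            r, p = stats.pearsonr(scores, df[pt].to_numpy())
            rows.append({"component": comp, "pt": pt, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def regress_pc1_on_lnror(result: PcaResult, overall_lnror: pd.Series) -> RegressionFit:
    """Ordinary least squares of the PC1 score on the per-drug lnROR of
    the combined (all-PT) chemosensory event.

    A strongly positive fit confirms that the first component tracks the
    overall reporting risk.
    """
    pc1 = result.component(1)
    common = pc1.index.intersection(overall_lnror.index)
    if len(common) < 3:
        raise DegenerateDataError(
            f"need at least 3 drugs shared between PCA scores and lnROR; got {len(common)}"
        )
    fit = stats.linregress(overall_lnror.loc[common], pc1.loc[common])
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def plot_dendrogram(result: ClusteringResult, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(result.labels))))
    dendrogram(result.linkage_matrix, labels=result.labels, orientation="left", ax=ax)
    ax.set_xlabel("Ward linkage distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pc1_regression(
    result: PcaResult, overall_lnror: pd.Series, path: str | Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = regress_pc1_on_lnror(result, overall_lnror)
    pc1 = result.component(1)
    common = pc1.index.intersection(overall_lnror.index)
    x = overall_lnror.loc[common]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, pc1.loc[common], s=18)
    xs = np.linspace(float(x.min()), float(x.max()), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, c="crimson",
            label=f"$R^2$ = {fit.r_squared:.3f}")
    ax.set_xlabel("lnROR (combined chemosensory event)")
    ax.set_ylabel("PC1 score")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
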