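"""Validation of ranked SL candidates against cell-line essentiality screens.

Essentiality scores follow the GARP convention: lower = more essential,
typical range roughly [+5, -10]. Validation surfaces: per-line
essentiality ranks, the reverse "GE rank" transform, rank-agreement
trends, top-quartile enrichment, and differential essentiality tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataValidationError, GeneLookupError
from .io_events import _check_unique, _read_table
from .mutex import SLCandidate

DEFECT_CODES = ("MUT", "DOWN", "HOMDEL")
DEFAULT_K = 5000


@dataclass
class GarpTable:
    """Gene x cell-line essentiality scores; NaN = not screened."""

    scores: pd.DataFrame  # float, genes x cell lines

    def __post_init__(self) -> None:
        _check_unique(list(self.scores.index), "gene symbol", "garp")
        _check_unique(list(self.scores.columns), "cell line", "garp")
        arr = self.scores.to_numpy()
        if arr.size and np.isinf(arr).any():
            raise DataValidationError("garp: non-finite score")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class CellLineAnnotation:
    """Deficiency annotation for one cell line.

    ``deficiencies`` maps gene-A symbol to its defect codes (a gene may
    carry several, e.g. MUT and DOWN).
    """

    cell_line: str
    deficiencies: dict[str, tuple[str, ...]] = field(default_factory=dict)
    is_control: bool = False

    def __post_init__(self) -> None:
        for gene, defects in self.deficiencies.items():
            for d in defects:
                if d not in DEFECT_CODES:
                    raise DataValidationError(
                        f"{self.cell_line}: unknown defect code {d!r} "
                        f"for gene {gene!r}"
                    )
        if not self.is_control and not self.deficiencies:
            raise DataValidationError(
                f"{self.cell_line}: non-control line must name at least "
                "one deficient gene A"
            )


@dataclass
class EnrichmentResult:
    """2x2 candidate x top-quartile contingency with Pearson chi-square."""

    table: np.ndarray  # rows: candidate/non-candidate; cols: top/not
    chi_square: float
    p_value: float
    quartile_size: int
    n_candidates_dropped: int
    dof: int = 1


@dataclass
class TrendResult:
    """Spearman agreement between ME ranks and GE ranks for one gene A.

    The paper-style "downward trend" (better ME rank pairs with higher
    GE rank, i.e. greater essentiality) corresponds to a negative
    coefficient.
    """

    cell_line: str
    gene_a: str
    pairs: list[tuple[int, int]]  # (me_rank, ge_rank)
    coefficient: float
    p_value: float
    n_pairs: int
    defined: bool


@dataclass
class DifferentialResult:
    test: str  # one-way-anova | paired-t
    groups: dict[str, int]  # group label -> n observations
    statistic: float
    p_value: float
    group_means: dict[str, float]
    degenerate: bool = False


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_garp_table(path: str | Path) -> GarpTable:
    """Read a GARP TSV (first column genes, header cell lines; NA allowed)."""
    genes, lines, rows = _read_table(path)
    clean = [[("nan" if c.strip() in ("", "NA", "NaN", "nan") else c)
              for c in row] for row in rows]
    try:
        arr = np.asarray(clean, dtype=float)
    except ValueError:
        raise DataValidationError(f"{path}: non-numeric GARP score") from None
    return GarpTable(pd.DataFrame(arr, index=genes, columns=lines, dtype=float))


def write_garp_table(garp: GarpTable, path: str | Path) -> None:
    garp.scores.to_csv(path, sep="\t", index_label="gene",
                       float_format="%.17g")


def read_cellline_annotations(path: str | Path) -> list[CellLineAnnotation]:
    """Read annotations: TSV columns cell_line, gene_a, defect, is_control.

    One row per (cell line, gene, defect); control lines may leave
    gene_a/defect empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["cell_line", "gene_a", "defect", "is_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    out: dict[str, CellLineAnnotation] = {}
    deficiencies: dict[str, dict[str, list[str]]] = {}
    controls: dict[str, bool] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        line = row["cell_line"].strip()
        if not line:
            raise DataValidationError(f"{path}: empty cell-line ID")
        if line not in controls:
            order.append(line)
            controls[line] = False
            deficiencies[line] = {}
        if row["is_control"].strip() in ("1", "true", "True", "yes"):
            controls[line] = True
        gene = row["gene_a"].strip()
        defect = row["defect"].strip()
        if gene or defect:
            if not (gene and defect):
                raise DataValidationError(
                    f"{path}: {line}: gene_a and defect must both be given"
                )
            deficiencies[line].setdefault(gene, [])
            if defect not in deficiencies[line][gene]:
                deficiencies[line][gene].append(defect)
    for line in order:
        out[line] = CellLineAnnotation(
            cell_line=line,
            deficiencies={g: tuple(d) for g, d in deficiencies[line].items()},
            is_control=controls[line],
        )
    return [out[line] for line in order]


def write_cellline_annotations(annotations: Sequence[CellLineAnnotation],
                               path: str | Path) -> None:
    rows = []
    for ann in annotations:
        if not ann.deficiencies:
            rows.append({"cell_line": ann.cell_line, "gene_a": "",
                         "defect": "", "is_control": int(ann.is_control)})
        for gene, defects in ann.deficiencies.items():
            for d in defects:
                rows.append({"cell_line": ann.cell_line, "gene_a": gene,
                             "defect": d, "is_control": int(ann.is_control)})
    pd.DataFrame(rows, columns=["cell_line", "gene_a", "defect",
                                "is_control"]).to_csv(path, sep="\t",
                                                      index=False)


# ---------------------------------------------------------------------------
# ranks
# ---------------------------------------------------------------------------

def essentiality_ranks(garp: GarpTable, cell_line: str) -> pd.Series:
    """Rank genes in one cell line; rank 1 = lowest (most essential) score.

    Ties break by lexicographic gene symbol; masked genes are omitted.
    """
    if cell_line not in garp.scores.columns:
        raise GeneLookupError(f"cell line {cell_line!r} not in GARP table")
    s = garp.scores[cell_line].dropna()
    ordered = sorted(s.items(), key=lambda kv: (kv[1], kv[0]))
    return pd.Series({gene: i + 1 for i, (gene, _) in enumerate(ordered)},
                     dtype=int, name=cell_line)


def ge_rank(rank: int, K: int = DEFAULT_K) -> int | None:
    """Reverse essentiality rank: K - rank for rank <= K, else excluded."""
    if rank < 1:
        raise ConfigError(f"rank must be >= 1, got {rank}")
    if rank > K:
        return None
    return K - rank


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (df 1, no continuity correction) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ConfigError("need a nonnegative 2x2 table")
    total = table.sum()
    if total == 0:
        raise DataValidationError("empty contingency table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected == 0).any():
        raise DataValidationError("degenerate margin in contingency table")
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def _top_quartile_sets(
    garp: GarpTable, cell_lines: Sequence[str], quartile_fraction: float
) -> dict[str, set[str]]:
    if not 0.0 < quartile_fraction < 1.0:
        raise ConfigError("quartile_fraction must be in (0, 1)")
    tops: dict[str, set[str]] = {}
    for line in cell_lines:
        ranks = essentiality_ranks(garp, line)
        q = int(np.floor(quartile_fraction * len(ranks)))
        tops[line] = set(ranks.index[ranks.to_numpy() <= q])
    return tops


def top_quartile_enrichment(
    candidate_genes: set[str] | Sequence[str],
    garp: GarpTable,
    cell_lines: Sequence[str],
    quartile_fraction: float = 0.25,
) -> EnrichmentResult:
    """Chi-square enrichment of candidates among top-quartile essential genes.

    Quartile membership is decided per cell line; the 2x2 table pools
    gene x line observations over the listed lines. Candidates absent
    from the screen are dropped (count reported).
    """
    candidates = set(candidate_genes)
    screen_genes = set(garp.genes)
    dropped = len(candidates - screen_genes)
    candidates &= screen_genes
    if not candidates:
        raise DataValidationError("no candidate gene overlaps the screen")
    tops = _top_quartile_sets(garp, cell_lines, quartile_fraction)
    table = np.zeros((2, 2), dtype=int)
    quartile_size = 0
    for line in cell_lines:
        scored = set(garp.scores[line].dropna().index)
        top = tops[line]
        quartile_size += len(top)
        for gene in scored:
            i = 0 if gene in candidates else 1
            j = 0 if gene in top else 1
            table[i, j] += 1
    stat, p = pearson_chi2(table)
    return EnrichmentResult(table=table, chi_square=stat, p_value=p,
                            quartile_size=quartile_size,
                            n_candidates_dropped=dropped)


def per_line_enrichment(
    candidate_genes: set[str] | Sequence[str],
    garp: GarpTable,
    cell_lines: Sequence[str],
    quartile_fraction: float = 0.25,
) -> dict[str, EnrichmentResult]:
    """Emit one enrichment result per cell line (unpooled mode)."""
    return {
        line: top_quartile_enrichment(candidate_genes, garp, [line],
                                      quartile_fraction)
        for line in cell_lines
    }


# ---------------------------------------------------------------------------
# rank-agreement trend
# ---------------------------------------------------------------------------

def me_ge_trend(
    ranked_candidates: Sequence[SLCandidate],
    garp: GarpTable,
    cell_line: str,
    K: int = DEFAULT_K,
    annotations: Sequence[CellLineAnnotation] | None = None,
) -> TrendResult:
    """Spearman correlation between ME ranks and GE ranks for one gene A.

    Only genes within the top K of the essentiality ranking contribute.
    Fewer than 3 pairs yields a flagged undefined result, not an error.
    When annotations are given, the cell line must be deficient in the
    candidates' gene A (the Fig-3-style pairing rule).
    """
    gene_as = {c.gene_a for c in ranked_candidates}
    if len(gene_as) != 1:
        raise ConfigError("trend needs candidates for exactly one gene A")
    gene_a = gene_as.pop()
    if any(c.me_rank is None for c in ranked_candidates):
        raise ConfigError("candidates must be ranked (me_rank set)")
    if annotations is not None:
        ann = {a.cell_line: a for a in annotations}.get(cell_line)
        if ann is None or gene_a not in ann.deficiencies:
            raise DataValidationError(
                f"cell line {cell_line!r} is not annotated deficient "
                f"in {gene_a!r}"
            )
    ranks = essentiality_ranks(garp, cell_line)
    pairs: list[tuple[int, int]] = []
    for c in ranked_candidates:
        r = ranks.get(c.gene_b)
        if r is None:
            continue
        ge = ge_rank(int(r), K)
        if ge is None:
            continue
        pairs.append((int(c.me_rank), ge))
    if len(pairs) < 3:
        return TrendResult(cell_line=cell_line, gene_a=gene_a, pairs=pairs,
                           coefficient=float("nan"), p_value=float("nan"),
                           n_pairs=len(pairs), defined=False)
    me, ge = zip(*pairs)
    rho, p = stats.spearmanr(me, ge)
    return TrendResult(cell_line=cell_line, gene_a=gene_a, pairs=pairs,
                       coefficient=float(rho), p_value=float(p),
                       n_pairs=len(pairs), defined=True)


# ---------------------------------------------------------------------------
# differential essentiality
# ---------------------------------------------------------------------------

def differential_essentiality(
    garp: GarpTable,
    genes_b: set[str] | Sequence[str],
    deficient_lines: Sequence[str],
    control_line: str,
) -> DifferentialResult:
    """One-way ANOVA of gene-B scores across deficient lines and a control."""
    if control_line in deficient_lines:
        raise ConfigError("control line must be distinct from deficient lines")
    genes = sorted(set(genes_b) & set(garp.genes))
    if not genes:
        raise DataValidationError("no gene B overlaps the screen")
    lines = list(deficient_lines) + [control_line]
    groups: list[np.ndarray] = []
    sizes: dict[str, int] = {}
    means: dict[str, float] = {}
    for line in lines:
        if line not in garp.scores.columns:
            raise GeneLookupError(f"cell line {line!r} not in GARP table")
        vec = garp.scores.loc[genes, line].dropna().to_numpy()
        if vec.size == 0:
            raise DataValidationError(
                f"cell line {line!r} has no unmasked scores for genes B"
            )
        groups.append(vec)
        sizes[line] = int(vec.size)
        means[line] = float(vec.mean())
    f, p = stats.f_oneway(*groups)
    return DifferentialResult(test="one-way-anova", groups=sizes,
                              statistic=float(f), p_value=float(p),
                              group_means=means)


def paired_differential(
    garp: GarpTable,
    genes_b: set[str] | Sequence[str],
    line_1: str,
    line_2: str,
) -> DifferentialResult:
    """Paired t-test over per-gene score differences between two lines.

    Identical vectors give t = 0, p = 1. Constant nonzero differences
    (zero variance) are flagged degenerate instead of returning an
    infinite statistic.
    """
    if line_1 == line_2:
        raise ConfigError("paired test needs two distinct cell lines")
    for line in (line_1, line_2):
        if line not in garp.scores.columns:
            raise GeneLookupError(f"cell line {line!r} not in GARP table")
    genes = sorted(set(genes_b) & set(garp.genes))
    sub = garp.scores.loc[genes, [line_1, line_2]].dropna()
    if len(sub) < 2:
        raise DataValidationError(
            f"fewer than 2 complete gene pairs between {line_1!r} and {line_2!r}"
        )
    x = sub[line_1].to_numpy()
    y = sub[line_2].to_numpy()
    sizes = {line_1: len(sub), line_2: len(sub)}
    means = {line_1: float(x.mean()), line_2: float(y.mean())}
    diffs = x - y
    if np.all(diffs == diffs[0]):
        if diffs[0] == 0:
            return DifferentialResult(test="paired-t", groups=sizes,
                                      statistic=0.0, p_value=1.0,
                                      group_means=means)
        return DifferentialResult(test="paired-t", groups=sizes,
                                  statistic=float("nan"),
                                  p_value=float("nan"),
                                  group_means=means, degenerate=True)
    t, p = stats.ttest_rel(x, y)
    return DifferentialResult(test="paired-t", groups=sizes,
                              statistic=float(t), p_value=float(p),
                              group_means=means)
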