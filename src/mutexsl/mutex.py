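"""Mutual-exclusivity scoring and candidate screening.

The exclusivity statistic for a gene pair is the hypergeometric lower
tail P[X <= n_ab] for the observed co-occurrence count, computed as a
log-space sum of the pmf to stay accurate for extreme exclusivity
(the complement form 1 - upper tail cancels catastrophically there;
the two forms are mathematically identical).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ConfigError, DataValidationError, GeneLookupError
from .io_events import AlterationProfile

CLASS_PAIRS = ("loss_gain", "loss_loss")
DEFAULT_ALPHA = {"loss_gain": 0.01, "loss_loss": 0.05}
CORRECTIONS = ("none", "benjamini-hochberg")
SCOPES = ("pooled", "per-cohort")

CANDIDATE_COLUMNS = [
    "gene_a", "class_a", "gene_b", "class_b",
    "n", "n_a", "n_b", "n_ab", "p_value", "me_rank", "cohort_scope",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """(|S|, |S_A|, |S_B|, |S_AB|) for one gene pair."""

    n: int
    n_a: int
    n_b: int
    n_ab: int

    def __post_init__(self) -> None:
        for name in ("n", "n_a", "n_b", "n_ab"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n_a > self.n or self.n_b > self.n:
            raise ConfigError(f"margins exceed population: {self}")
        if self.n_ab > min(self.n_a, self.n_b):
            raise ConfigError(f"overlap exceeds a margin: {self}")
        if self.n_a + self.n_b - self.n_ab > self.n:
            raise ConfigError(f"inclusion-exclusion violated: {self}")


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def mutex_pvalue(c: ContingencyCounts) -> float:
    """Exclusivity p-value: hypergeometric P[X <= n_ab].

    X counts the overlap when n_b samples are drawn without replacement
    from a population of n with n_a marked. Result is in (0, 1].
    """
    if c.n_ab == min(c.n_a, c.n_b):  # full support: upper tail is empty
        return 1.0
    lo = max(0, c.n_a + c.n_b - c.n)
    k = np.arange(lo, c.n_ab + 1)
    log_pmf = (
        _log_binom(c.n_a, k)
        + _log_binom(c.n - c.n_a, c.n_b - k)
        - _log_binom(c.n, c.n_b)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


@dataclass(frozen=True)
class SLCandidate:
    """One scored (gene A, gene B) pair."""

    gene_a: str
    class_a: str
    gene_b: str
    class_b: str
    counts: ContingencyCounts
    p_value: float
    cohort_scope: str
    me_rank: int | None = None
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if self.gene_b == self.gene_a:
            raise ConfigError(f"self-pair {self.gene_a!r}")
        if not 0.0 < self.p_value <= 1.0:
            raise DataValidationError(
                f"p-value {self.p_value} outside (0, 1] for "
                f"{self.gene_a}/{self.gene_b}"
            )


@dataclass
class ScreenConfig:
    """Parameters of one exclusivity screen.

    ``alpha`` defaults per interaction class (0.01 for loss_gain, 0.05
    for loss_loss). P-values are uncorrected by default; rank-based use
    downstream is the intended consumer. Benjamini-Hochberg selection is
    available but off by default.
    """

    gene_a_panel: Sequence[str]
    class_pair: str = "loss_gain"
    alpha: float | None = None
    scope: str = "pooled"
    correction: str = "none"
    min_event_count: int = 1
    include_panel_as_b: bool = False

    def __post_init__(self) -> None:
        if self.class_pair not in CLASS_PAIRS:
            raise ConfigError(f"class_pair must be one of {CLASS_PAIRS}")
        if self.alpha is None:
            self.alpha = DEFAULT_ALPHA[self.class_pair]
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.scope not in SCOPES:
            raise ConfigError(f"scope must be one of {SCOPES}")
        if self.correction not in CORRECTIONS:
            raise ConfigError(f"correction must be one of {CORRECTIONS}")
        if self.min_event_count < 1:
            raise ConfigError("min_event_count must be >= 1")
        if not self.gene_a_panel:
            raise ConfigError("gene_a_panel is empty")

    @property
    def class_b(self) -> str:
        return "gain" if self.class_pair == "loss_gain" else "loss"


def _class_matrix(profile: AlterationProfile, cls: str) -> pd.DataFrame:
    if cls == "loss":
        return profile.loss_calls
    if cls == "gain":
        return profile.gain_calls
    raise ConfigError(f"event class must be 'loss' or 'gain', got {cls!r}")


def count_cooccurrence(
    profile: AlterationProfile,
    gene_a: str,
    class_a: str,
    gene_b: str,
    class_b: str,
) -> ContingencyCounts:
    """Count (n, n_a, n_b, n_ab) over the profile's sample universe."""
    if gene_a == gene_b:
        raise ConfigError(f"self-pair {gene_a!r}")
    mat_a = _class_matrix(profile, class_a)
    mat_b = _class_matrix(profile, class_b)
    for gene in (gene_a, gene_b):
        if gene not in mat_a.index:
            raise GeneLookupError(f"gene {gene!r} not in profile")
    a = mat_a.loc[gene_a].to_numpy()
    b = mat_b.loc[gene_b].to_numpy()
    return ContingencyCounts(
        n=profile.n_union,
        n_a=int(a.sum()),
        n_b=int(b.sum()),
        n_ab=int((a & b).sum()),
    )


def screen_pairs(
    profile: AlterationProfile,
    config: ScreenConfig,
    gene_b_universe: Sequence[str] | str = "all",
) -> list[SLCandidate]:
    """Score every eligible (panel gene A, gene B) pair.

    Pairs need n_a and n_b >= min_event_count; pairs with p <= alpha
    (adjusted p when Benjamini-Hochberg is on) are returned in a
    deterministic order (panel order, then gene B alphabetically).
    """
    panel = list(config.gene_a_panel)
    gene_set = set(profile.genes)
    missing = [g for g in panel if g not in gene_set]
    if missing:
        raise GeneLookupError(f"panel genes not in profile: {missing}")
    if gene_b_universe == "all":
        excluded = set() if config.include_panel_as_b else set(panel)
        universe = sorted(g for g in profile.genes if g not in excluded)
    else:
        universe = sorted(gene_b_universe)
        missing = [g for g in universe if g not in gene_set]
        if missing:
            raise GeneLookupError(f"universe genes not in profile: {missing}")

    loss = profile.loss_calls
    mat_b = _class_matrix(profile, config.class_b)
    b_sub = mat_b.loc[universe]
    b_arr = b_sub.to_numpy().astype(np.int64)  # bool @ bool is logical, not a count
    n_b_all = b_arr.sum(axis=1)
    n = profile.n_union

    tested: list[tuple[str, str, ContingencyCounts, float]] = []
    for gene_a in panel:
        a = loss.loc[gene_a].to_numpy().astype(np.int64)
        n_a = int(a.sum())
        if n_a < config.min_event_count:
            continue
        n_ab_all = b_arr @ a
        for j, gene_b in enumerate(universe):
            if gene_b == gene_a:
                continue
            n_b = int(n_b_all[j])
            if n_b < config.min_event_count:
                continue
            counts = ContingencyCounts(n, n_a, n_b, int(n_ab_all[j]))
            tested.append((gene_a, gene_b, counts, mutex_pvalue(counts)))

    if not tested:
        return []
    pvals = np.array([t[3] for t in tested])
    if config.correction == "benjamini-hochberg":
        from statsmodels.stats.multitest import multipletests

        keep, p_adj, _, _ = multipletests(pvals, alpha=config.alpha,
                                          method="fdr_bh")
    else:
        keep = pvals <= config.alpha
        p_adj = [None] * len(tested)

    scope = profile.cohort
    return [
        SLCandidate(
            gene_a=ga, class_a="loss", gene_b=gb, class_b=config.class_b,
            counts=counts, p_value=p, cohort_scope=scope,
            p_adjusted=(None if adj is None else float(adj)),
        )
        for (ga, gb, counts, p), ok, adj in zip(tested, keep, p_adj)
        if ok
    ]


def rank_by_me(candidates: Sequence[SLCandidate]) -> list[SLCandidate]:
    """Assign ME ranks 1..N by ascending p-value.

    Ties break by descending n_b (favouring more frequently altered
    partners), then lexicographic gene_b, then gene_a — deterministic
    and unique.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (c.p_value, -c.counts.n_b, c.gene_b, c.gene_a),
    )
    return [replace(c, me_rank=i + 1) for i, c in enumerate(ordered)]


def summarize_by_geneA(
    candidates: Sequence[SLCandidate], alphas: Sequence[float]
) -> pd.DataFrame:
    """Per-gene-A proportions of interactions at each alpha.

    Rows are genes A, columns alphas; each column sums to 1 over the
    candidates passing that threshold. An empty candidate list (or an
    alpha no candidate passes) yields an empty/NaN-free column of zeros
    only when some other alpha is populated; a fully empty input yields
    an empty table.
    """
    if not candidates:
        return pd.DataFrame(columns=[float(a) for a in alphas])
    gene_as = sorted({c.gene_a for c in candidates})
    table = pd.DataFrame(0.0, index=gene_as, columns=[float(a) for a in alphas])
    for alpha in alphas:
        passing = [c for c in candidates if c.p_value <= alpha]
        if not passing:
            continue
        counts = pd.Series([c.gene_a for c in passing]).value_counts()
        table[float(alpha)] = counts.reindex(gene_as, fill_value=0) / len(passing)
    table.index.name = "gene_a"
    return table


# ---------------------------------------------------------------------------
# candidate table I/O
# ---------------------------------------------------------------------------

def candidates_to_frame(candidates: Sequence[SLCandidate]) -> pd.DataFrame:
    rows = [
        {
            "gene_a": c.gene_a, "class_a": c.class_a,
            "gene_b": c.gene_b, "class_b": c.class_b,
            "n": c.counts.n, "n_a": c.counts.n_a,
            "n_b": c.counts.n_b, "n_ab": c.counts.n_ab,
            "p_value": c.p_value,
            "me_rank": c.me_rank if c.me_rank is not None else "",
            "cohort_scope": c.cohort_scope,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates(candidates: Sequence[SLCandidate],
                     path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[SLCandidate]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    out: list[SLCandidate] = []
    for _, row in df.iterrows():
        rank = row["me_rank"]
        out.append(
            SLCandidate(
                gene_a=str(row["gene_a"]), class_a=str(row["class_a"]),
                gene_b=str(row["gene_b"]), class_b=str(row["class_b"]),
                counts=ContingencyCounts(int(row["n"]), int(row["n_a"]),
                                         int(row["n_b"]), int(row["n_ab"])),
                p_value=float(row["p_value"]),
                cohort_scope=str(row["cohort_scope"]),
                me_rank=None if pd.isna(rank) or rank == "" else int(rank),
            )
        )
    return out
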