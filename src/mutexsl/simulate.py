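"""Seeded synthetic cohorts and essentiality screens with planted structure.

Cohorts carry planted mutually exclusive gene pairs whose joint
alteration probability is epsilon * f_a * f_b (epsilon 1 = independent,
0 = perfectly exclusive); screens depress the scores of planted SL
partners in lines deficient for their gene A. Every generator is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import ConfigError, DataValidationError
from .io_events import (
    ExpressionZMatrix,
    GisticMatrix,
    call_copy_number_events,
    call_expression_events,
    merge_alterations,
)
from .mutex import SLCandidate, count_cooccurrence, rank_by_me


@dataclass(frozen=True)
class PlantedPair:
    """One planted pair: gene A loss at f_a, gene B (class_b) at f_b."""

    gene_a: str
    f_a: float
    gene_b: str
    f_b: float
    epsilon: float
    class_b: str = "gain"

    def __post_init__(self) -> None:
        for name in ("f_a", "f_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigError(f"epsilon must be in [0,1], got {self.epsilon}")
        if self.class_b not in ("gain", "loss"):
            raise ConfigError(f"class_b must be 'gain' or 'loss'")
        if self.gene_a == self.gene_b:
            raise ConfigError(f"planted self-pair {self.gene_a!r}")
        # joint law feasibility: all four cell probabilities nonnegative
        p11 = self.epsilon * self.f_a * self.f_b
        p00 = 1.0 - self.f_a - self.f_b + p11
        if p00 < -1e-12:
            raise ConfigError(
                f"infeasible 2x2 for pair ({self.gene_a}, {self.gene_b}): "
                f"P(neither) = {p00:.4f} < 0"
            )


@dataclass
class CohortSimConfig:
    """Configuration of one synthetic cohort."""

    n_samples: int
    seed: int
    frac_genomic_only: float = 0.25
    frac_expression_only: float = 0.25
    frac_both: float = 0.5
    n_background_genes: int = 100
    planted_pairs: tuple[PlantedPair, ...] = ()
    background_event_freq: float = 0.05
    channel_split: float = 0.5
    z_threshold: float = 2.0
    low_level_rate: float = 0.05
    cohort: str = "sim"

    def __post_init__(self) -> None:
        self.planted_pairs = tuple(self.planted_pairs)
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        fracs = (self.frac_genomic_only, self.frac_expression_only,
                 self.frac_both)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError("assay fractions must be nonnegative and sum to 1")
        if not 0.0 <= self.background_event_freq <= 0.5:
            raise ConfigError("background_event_freq must be in [0, 0.5]")
        if not 0.0 <= self.channel_split <= 1.0:
            raise ConfigError("channel_split must be in [0, 1]")
        if self.z_threshold <= 0:
            raise ConfigError("z_threshold must be positive")
        f_a_by_gene: dict[str, float] = {}
        partners_seen: set[str] = set()
        a_genes = {p.gene_a for p in self.planted_pairs}
        for p in self.planted_pairs:
            prev = f_a_by_gene.setdefault(p.gene_a, p.f_a)
            if prev != p.f_a:
                raise ConfigError(
                    f"gene A {p.gene_a!r} planted with conflicting f_a"
                )
            if p.gene_b in partners_seen:
                raise ConfigError(f"gene B {p.gene_b!r} planted twice")
            if p.gene_b in a_genes:
                raise ConfigError(
                    f"gene {p.gene_b!r} appears as both gene A and gene B"
                )
            partners_seen.add(p.gene_b)


@dataclass
class TruthTable:
    """Planted pairs and their realized counts, recounted from the output."""

    planted: tuple[PlantedPair, ...]
    realized: pd.DataFrame  # gene_a, gene_b, class_pair, epsilon, n, n_a, n_b, n_ab
    genes: list[str]
    background_genes: list[str]

    def write(self, path: str | Path) -> None:
        self.realized.to_csv(path, sep="\t", index=False)


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[GisticMatrix, ExpressionZMatrix, TruthTable]:
    """Generate one cohort; same (config, seed) gives bit-identical output.

    Per planted pair, per-sample joint states follow the 2x2 law with
    P(both) = epsilon * f_a * f_b. Each alteration materializes on the
    copy-number channel with probability channel_split when the sample
    has both assays, otherwise on whichever assay the sample has, so
    configured margins are preserved. Unaltered z-scores are drawn from
    Normal(0,1) truncated inside (-t, t); altered magnitudes are
    t + Exponential(1).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = config.z_threshold
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    avail = rng.choice(
        3, size=n,
        p=[config.frac_genomic_only, config.frac_expression_only,
           config.frac_both],
    )
    has_cn = (avail == 0) | (avail == 2)
    has_ex = (avail == 1) | (avail == 2)

    # planted gene states: each gene A drawn once, partners conditional on it
    gene_states: dict[str, tuple[str, np.ndarray]] = {}
    for pair in config.planted_pairs:
        if pair.gene_a not in gene_states:
            gene_states[pair.gene_a] = (
                "loss", rng.random(n) < pair.f_a
            )
        a_state = gene_states[pair.gene_a][1]
        p_b_given_a1 = pair.epsilon * pair.f_b
        if pair.f_a < 1.0:
            p_b_given_a0 = (pair.f_b * (1.0 - pair.epsilon * pair.f_a)
                            / (1.0 - pair.f_a))
        else:
            p_b_given_a0 = 0.0
        u = rng.random(n)
        b_state = np.where(a_state, u < p_b_given_a1, u < p_b_given_a0)
        gene_states[pair.gene_b] = (pair.class_b, b_state)

    background = [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    r = config.background_event_freq
    for gene in background:
        u = rng.random(n)
        # trinary state keeps loss/gain disjoint per cell
        gene_states[gene] = ("both", u)  # resolved below

    genes = list(gene_states)
    cn_rows = np.zeros((len(genes), n), dtype=int)
    z_rows = np.empty((len(genes), n), dtype=float)

    lo, hi = ndtr(-t), ndtr(t)
    for i, gene in enumerate(genes):
        cls, state = gene_states[gene]
        if cls == "both":
            loss_state = state < r
            gain_state = (state >= r) & (state < 2 * r)
        elif cls == "loss":
            loss_state, gain_state = state, np.zeros(n, dtype=bool)
        else:
            loss_state, gain_state = np.zeros(n, dtype=bool), state
        altered = loss_state | gain_state
        sign = np.where(loss_state, -1, 1)

        channel_draw = rng.random(n) < config.channel_split
        use_cn = altered & has_cn & (~has_ex | channel_draw)
        use_ex = altered & has_ex & ~use_cn

        row = np.zeros(n, dtype=int)
        row[use_cn] = 2 * sign[use_cn]
        # low-level +/-1 noise on otherwise neutral genomic cells
        noise = has_cn & (row == 0) & (rng.random(n) < config.low_level_rate)
        row[noise] = rng.choice((-1, 1), size=int(noise.sum()))
        cn_rows[i] = row

        z = ndtri(rng.uniform(lo, hi, n))
        mag = t + rng.exponential(1.0, n)
        z = np.where(use_ex, sign * mag, z)
        z_rows[i] = z

    gm = GisticMatrix(
        pd.DataFrame(cn_rows, index=genes, columns=samples).loc[:, has_cn],
        config.cohort,
    )
    zm = ExpressionZMatrix(
        pd.DataFrame(z_rows, index=genes, columns=samples).loc[:, has_ex],
        config.cohort,
    )

    profile = merge_alterations(
        call_copy_number_events(gm),
        call_expression_events(zm, config.z_threshold),
    )
    records = []
    for pair in config.planted_pairs:
        c = count_cooccurrence(profile, pair.gene_a, "loss",
                               pair.gene_b, pair.class_b)
        records.append({
            "gene_a": pair.gene_a, "gene_b": pair.gene_b,
            "class_pair": f"loss_{pair.class_b}", "epsilon": pair.epsilon,
            "n": c.n, "n_a": c.n_a, "n_b": c.n_b, "n_ab": c.n_ab,
        })
    realized = pd.DataFrame(
        records, columns=["gene_a", "gene_b", "class_pair", "epsilon",
                          "n", "n_a", "n_b", "n_ab"],
    )
    truth = TruthTable(planted=config.planted_pairs, realized=realized,
                       genes=genes, background_genes=background)
    return gm, zm, truth


# ---------------------------------------------------------------------------
# essentiality screen simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Configuration of one synthetic essentiality screen."""

    n_genes: int
    seed: int
    deficiency_map: Mapping[str, str] = field(default_factory=dict)
    control_lines: tuple[str, ...] = ("CTRL",)
    mu0: float = 0.0
    sd0: float = 1.5
    essentiality_shift: float = 3.0
    score_min: float = -10.0
    score_max: float = 5.0

    def __post_init__(self) -> None:
        self.deficiency_map = dict(self.deficiency_map)
        self.control_lines = tuple(self.control_lines)
        if self.essentiality_shift <= 0:
            raise ConfigError("essentiality_shift must be positive")
        overlap = set(self.deficiency_map) & set(self.control_lines)
        if overlap:
            raise ConfigError(
                f"lines both deficient and control: {sorted(overlap)}"
            )
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")

    @property
    def n_cell_lines(self) -> int:
        return len(self.deficiency_map) + len(self.control_lines)


def simulate_screen(config: ScreenSimConfig, truth: TruthTable):
    """Generate a GARP-like score table plus annotations.

    Background scores are i.i.d. Normal(mu0, sd0) clipped to the GARP
    range; each deficient line has the scores of its gene A's planted
    partners shifted down by essentiality_shift.
    """
    from .validation import CellLineAnnotation, GarpTable

    planted_as = {p.gene_a for p in truth.planted}
    for line, gene_a in config.deficiency_map.items():
        if gene_a not in planted_as:
            raise DataValidationError(
                f"deficiency map names gene A {gene_a!r} absent from truth"
            )
    rng = np.random.default_rng(config.seed)
    if config.n_genes < len(truth.genes):
        raise ConfigError(
            f"n_genes={config.n_genes} smaller than the cohort's "
            f"{len(truth.genes)} genes"
        )
    genes = list(truth.genes) + [
        f"XG{i:04d}" for i in range(1, config.n_genes - len(truth.genes) + 1)
    ]
    lines = list(config.deficiency_map) + list(config.control_lines)
    scores = rng.normal(config.mu0, config.sd0, (len(genes), len(lines)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    partners_of = {
        a: [p.gene_b for p in truth.planted if p.gene_a == a]
        for a in planted_as
    }
    for j, line in enumerate(lines):
        gene_a = config.deficiency_map.get(line)
        if gene_a is None:
            continue
        for gb in partners_of[gene_a]:
            scores[gene_idx[gb], j] -= config.essentiality_shift
    scores = scores.clip(config.score_min, config.score_max)
    garp = GarpTable(pd.DataFrame(scores, index=genes, columns=lines))
    annotations = []
    for line in lines:
        gene_a = config.deficiency_map.get(line)
        if gene_a is None:
            annotations.append(CellLineAnnotation(cell_line=line,
                                                  is_control=True))
        else:
            defect = str(rng.choice(("MUT", "DOWN", "HOMDEL")))
            annotations.append(CellLineAnnotation(
                cell_line=line, deficiencies={gene_a: (defect,)}))
    return garp, annotations


# ---------------------------------------------------------------------------
# truth-aware recovery metrics
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    planted_ranks: dict[tuple[str, str], int | None]
    fraction_top_m: float | None
    top_m: int | None
    background_fpr: float
    n_background_pairs: int
    alpha: float


def recovery_metrics(
    candidates: Sequence[SLCandidate],
    truth: TruthTable,
    alpha: float = 0.05,
    top_m: int | None = None,
) -> RecoveryMetrics:
    """Rank recovery of planted pairs and background false-positive rate.

    The candidate list should come from an alpha = 1 screen so every
    tested pair is present; the FPR is the fraction of non-planted pairs
    with p <= alpha. Planted pairs absent from the candidate list map to
    rank None.
    """
    if candidates and not set(c.gene_b for c in candidates) & set(truth.genes):
        raise DataValidationError("candidates and truth share no genes")
    ranked = list(candidates)
    if any(c.me_rank is None for c in ranked):
        ranked = rank_by_me(ranked)
    planted_keys = {(p.gene_a, p.gene_b) for p in truth.planted}
    rank_of = {(c.gene_a, c.gene_b): c.me_rank for c in ranked}
    planted_ranks = {key: rank_of.get(key) for key in sorted(planted_keys)}
    background = [c for c in ranked if (c.gene_a, c.gene_b) not in planted_keys]
    n_bg = len(background)
    fpr = (sum(c.p_value <= alpha for c in background) / n_bg) if n_bg else 0.0
    if planted_keys:
        m = top_m if top_m is not None else len(planted_keys)
        found = sum(
            1 for r in planted_ranks.values() if r is not None and r <= m
        )
        frac = found / len(planted_keys)
    else:
        m, frac = None, None
    return RecoveryMetrics(planted_ranks=planted_ranks, fraction_top_m=frac,
                           top_m=m, background_fpr=fpr,
                           n_background_pairs=n_bg, alpha=alpha)
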