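"""Cohort matrix I/O and binary alteration-event calling.

Reads gene x sample matrices (discretized copy number and expression
z-scores) in a cBioPortal/Firehose-style TSV layout, calls the four
event types (AMP, DEL, UP, DOWN), and merges them into composite
loss/gain profiles over a pooled multi-assay sample universe.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataValidationError, ParseError

GISTIC_CODES = (-2, -1, 0, 1, 2)
EVENT_TYPES = ("AMP", "DEL", "UP", "DOWN")
ASSAYS = ("copy_number", "expression")

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "NAN", "NULL", "null", "None"}


# ---------------------------------------------------------------------------
# low-level TSV plumbing
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> tuple[list[str], list[str], list[list[str]]]:
    """Read a gene-major TSV; enforce rectangular shape and unique labels.

    Returns (genes, samples, rows-of-strings).
    """
    path = Path(path)
    try:
        fh = open(path, newline="")
    except OSError as exc:
        raise ParseError(f"{path}: cannot open ({exc})") from exc
    with fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        width = len(header)
        if width < 1:
            raise ParseError(f"{path}: header row is empty")
        genes: list[str] = []
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:  # trailing blank line
                continue
            if len(row) != width:
                raise ParseError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {width}"
                )
            genes.append(row[0])
            rows.append(row[1:])
    samples = header[1:]
    _check_unique(genes, "gene symbol", path)
    _check_unique(samples, "sample ID", path)
    return genes, samples, rows


def _check_unique(labels: Sequence[str], what: str, context: object) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DataValidationError(f"{context}: duplicate {what} {lab!r}")
        seen.add(lab)


def _first_bad_cell(rows, genes, samples, predicate) -> tuple[str, str, str]:
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if predicate(cell):
                return genes[i], samples[j], cell
    raise AssertionError("no offending cell found")  # pragma: no cover


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GisticMatrix:
    """Discretized copy-number matrix with entries in {-2,-1,0,1,2}."""

    values: pd.DataFrame  # int, genes x samples
    cohort: str

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene symbol", self.cohort)
        _check_unique(list(self.values.columns), "sample ID", self.cohort)
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, GISTIC_CODES).all():
            bad = np.argwhere(~np.isin(arr, GISTIC_CODES))[0]
            raise DataValidationError(
                f"{self.cohort}: copy-number value {arr[tuple(bad)]!r} out of range "
                f"for gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionZMatrix:
    """Expression z-score matrix; NaN entries are masked as missing."""

    values: pd.DataFrame  # float, genes x samples, NaN = missing
    cohort: str

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene symbol", self.cohort)
        _check_unique(list(self.values.columns), "sample ID", self.cohort)
        arr = self.values.to_numpy()
        if arr.size and np.isinf(arr).any():
            bad = np.argwhere(np.isinf(arr))[0]
            raise DataValidationError(
                f"{self.cohort}: non-finite z-score for gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass
class EventMatrix:
    """Boolean gene x sample calls for one event type."""

    event_type: str  # AMP | DEL | UP | DOWN
    calls: pd.DataFrame  # bool
    assay: str  # copy_number | expression
    cohort: str

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ConfigError(f"unknown event type {self.event_type!r}")
        if self.assay not in ASSAYS:
            raise ConfigError(f"unknown assay {self.assay!r}")
        if self.calls.dtypes.ne(bool).any():
            raise DataValidationError(
                f"{self.cohort}/{self.event_type}: calls must be boolean"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class AlterationProfile:
    """Composite loss (DEL∪DOWN) / gain (AMP∪UP) calls over pooled samples.

    A sample lacking an assay contributes no events of that assay; it is
    treated as event-free there, not missing-at-random.
    """

    loss_calls: pd.DataFrame  # bool, genes x universe
    gain_calls: pd.DataFrame  # bool, genes x universe
    assay_available: pd.DataFrame  # bool, universe x ASSAYS
    cohort: str

    def __post_init__(self) -> None:
        if not self.loss_calls.index.equals(self.gain_calls.index):
            raise DataValidationError("loss/gain gene indices differ")
        if not self.loss_calls.columns.equals(self.gain_calls.columns):
            raise DataValidationError("loss/gain sample universes differ")
        if not self.loss_calls.columns.equals(self.assay_available.index):
            raise DataValidationError("assay availability does not match universe")

    @property
    def genes(self) -> list[str]:
        return list(self.loss_calls.index)

    @property
    def universe(self) -> list[str]:
        return list(self.loss_calls.columns)

    @property
    def n_union(self) -> int:
        return self.loss_calls.shape[1]

    @property
    def n_genomic(self) -> int:
        return int(self.assay_available["copy_number"].sum())

    @property
    def n_expression(self) -> int:
        return int(self.assay_available["expression"].sum())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_gistic_matrix(path: str | Path, cohort: str) -> GisticMatrix:
    """Read a GISTIC-discretized TSV (first column genes, header samples)."""
    genes, samples, rows = _read_table(path)
    try:
        arr = np.asarray(rows, dtype=float)
    except ValueError:
        g, s, cell = _first_bad_cell(
            rows, genes, samples, lambda c: not _is_number(c)
        )
        raise ParseError(
            f"{path}: non-numeric copy-number value {cell!r} "
            f"(gene {g!r}, sample {s!r})"
        ) from None
    if arr.size and (np.isnan(arr).any() or (arr != np.round(arr)).any()):
        g, s, cell = _first_bad_cell(
            rows, genes, samples,
            lambda c: not _is_number(c) or float(c) != round(float(c)),
        )
        raise ParseError(
            f"{path}: copy-number value {cell!r} is not an integer "
            f"(gene {g!r}, sample {s!r})"
        )
    df = pd.DataFrame(arr.astype(int) if arr.size else arr,
                      index=genes, columns=samples, dtype=int)
    try:
        return GisticMatrix(df, cohort)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from None


def read_zscore_matrix(path: str | Path, cohort: str) -> ExpressionZMatrix:
    """Read an expression z-score TSV; empty/NA cells become missing."""
    genes, samples, rows = _read_table(path)
    clean = [[("nan" if c.strip() in _MISSING_TOKENS else c) for c in row]
             for row in rows]
    try:
        arr = np.asarray(clean, dtype=float)
    except ValueError:
        g, s, cell = _first_bad_cell(
            rows, genes, samples,
            lambda c: c.strip() not in _MISSING_TOKENS and not _is_number(c),
        )
        raise ParseError(
            f"{path}: non-numeric z-score {cell!r} (gene {g!r}, sample {s!r})"
        ) from None
    df = pd.DataFrame(arr, index=genes, columns=samples, dtype=float)
    try:
        return ExpressionZMatrix(df, cohort)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from None


def _is_number(cell: str) -> bool:
    try:
        float(cell)
    except ValueError:
        return False
    return not np.isnan(float(cell))


def write_matrix_tsv(df: pd.DataFrame, path: str | Path,
                     index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_event_matrix(em: EventMatrix, path: str | Path) -> None:
    """Write boolean calls as a 0/1 TSV."""
    write_matrix_tsv(em.calls.astype(int), path)


def read_event_matrix(path: str | Path, event_type: str, assay: str,
                      cohort: str) -> EventMatrix:
    genes, samples, rows = _read_table(path)
    try:
        arr = np.asarray(rows, dtype=float)
    except ValueError:
        raise ParseError(f"{path}: non-numeric event call") from None
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ParseError(f"{path}: event calls must be 0/1")
    df = pd.DataFrame(arr.astype(bool) if arr.size else arr.astype(bool),
                      index=genes, columns=samples)
    return EventMatrix(event_type, df, assay, cohort)


def read_gene_panel(path: str | Path) -> list[str]:
    """Read a gene panel: one symbol per line, '#' comments and blanks allowed."""
    panel: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                panel.append(sym)
    _check_unique(panel, "panel gene", path)
    if not panel:
        raise ConfigError(f"{path}: gene panel is empty")
    return panel


# ---------------------------------------------------------------------------
# event calling
# ---------------------------------------------------------------------------

def call_copy_number_events(m: GisticMatrix) -> tuple[EventMatrix, EventMatrix]:
    """AMP iff value == +2, DEL iff value == -2 (high-level events only)."""
    amp = EventMatrix("AMP", m.values.eq(2), "copy_number", m.cohort)
    dele = EventMatrix("DEL", m.values.eq(-2), "copy_number", m.cohort)
    return amp, dele


def call_expression_events(
    m: ExpressionZMatrix, z_threshold: float = 2.0
) -> tuple[EventMatrix, EventMatrix]:
    """UP iff z >= +threshold, DOWN iff z <= -threshold (inclusive).

    Missing cells never generate events.
    """
    if not z_threshold > 0:
        raise ConfigError(f"z_threshold must be positive, got {z_threshold}")
    present = m.values.notna()
    up = EventMatrix("UP", m.values.ge(z_threshold) & present,
                     "expression", m.cohort)
    down = EventMatrix("DOWN", m.values.le(-z_threshold) & present,
                       "expression", m.cohort)
    return up, down


# ---------------------------------------------------------------------------
# merging into composite profiles
# ---------------------------------------------------------------------------

def merge_alterations(
    cn_events: tuple[EventMatrix, EventMatrix] | None = None,
    expr_events: tuple[EventMatrix, EventMatrix] | None = None,
) -> AlterationProfile:
    """Merge per-assay event matrices into one loss/gain profile.

    The sample universe S is the union of copy-number and expression
    sample IDs (each sample appears once even if assayed twice);
    loss = DEL ∪ DOWN and gain = AMP ∪ UP.
    """
    if cn_events is None and expr_events is None:
        raise ConfigError("merge_alterations needs at least one assay")
    mats: list[EventMatrix] = []
    if cn_events is not None:
        amp, dele = cn_events
        if amp.event_type != "AMP" or dele.event_type != "DEL":
            raise ConfigError("cn_events must be the (AMP, DEL) pair")
        mats += [amp, dele]
    if expr_events is not None:
        up, down = expr_events
        if up.event_type != "UP" or down.event_type != "DOWN":
            raise ConfigError("expr_events must be the (UP, DOWN) pair")
        mats += [up, down]
    cohorts = {m.cohort for m in mats}
    if len(cohorts) > 1:
        raise DataValidationError(f"conflicting cohort labels: {sorted(cohorts)}")
    cohort = cohorts.pop()

    genes = _ordered_union(m.genes for m in mats)
    cn_samples = mats[0].samples if cn_events is not None else []
    ex_samples = mats[-1].samples if expr_events is not None else []
    universe = _ordered_union([cn_samples, ex_samples])

    def expand(ems: Iterable[EventMatrix]) -> pd.DataFrame:
        out = pd.DataFrame(False, index=genes, columns=universe)
        for em in ems:
            aligned = em.calls.reindex(index=genes, columns=universe,
                                       fill_value=False)
            out |= aligned
        return out

    loss_sources = [m for m in mats if m.event_type in ("DEL", "DOWN")]
    gain_sources = [m for m in mats if m.event_type in ("AMP", "UP")]
    avail = pd.DataFrame(False, index=universe, columns=list(ASSAYS))
    avail.loc[cn_samples, "copy_number"] = True
    avail.loc[ex_samples, "expression"] = True
    return AlterationProfile(expand(loss_sources), expand(gain_sources),
                             avail, cohort)


def _ordered_union(groups: Iterable[Sequence[str]]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for group in groups:
        for item in group:
            if item not in seen:
                seen.add(item)
                out.append(item)
    return out


def pool_profiles(profiles: Sequence[AlterationProfile],
                  label: str = "pooled") -> AlterationProfile:
    """Concatenate per-cohort profiles into one pooled sample universe.

    Sample IDs must be disjoint across cohorts (TCGA barcodes are); a
    collision is an error rather than a silent merge.
    """
    if not profiles:
        raise ConfigError("no profiles to pool")
    if len(profiles) == 1:
        p = profiles[0]
        return AlterationProfile(p.loss_calls.copy(), p.gain_calls.copy(),
                                 p.assay_available.copy(), label)
    seen: set[str] = set()
    for p in profiles:
        overlap = seen.intersection(p.universe)
        if overlap:
            raise DataValidationError(
                f"sample IDs shared across cohorts: {sorted(overlap)[:5]}"
            )
        seen.update(p.universe)
    genes = _ordered_union(p.genes for p in profiles)
    loss = pd.concat(
        [p.loss_calls.reindex(index=genes, fill_value=False) for p in profiles],
        axis=1,
    )
    gain = pd.concat(
        [p.gain_calls.reindex(index=genes, fill_value=False) for p in profiles],
        axis=1,
    )
    avail = pd.concat([p.assay_available for p in profiles], axis=0)
    return AlterationProfile(loss, gain, avail, label)


def cohort_manifest(profiles: Sequence[AlterationProfile]) -> pd.DataFrame:
    """Per-cohort sample accounting plus a grand-total row.

    Columns: cohort, n_genomic, n_expression, n_union. The total row sums
    each column over cohorts.
    """
    rows = [
        {
            "cohort": p.cohort,
            "n_genomic": p.n_genomic,
            "n_expression": p.n_expression,
            "n_union": p.n_union,
        }
        for p in profiles
    ]
    df = pd.DataFrame(rows, columns=["cohort", "n_genomic", "n_expression",
                                     "n_union"])
    total = {
        "cohort": "total",
        "n_genomic": int(df["n_genomic"].sum()),
        "n_expression": int(df["n_expression"].sum()),
        "n_union": int(df["n_union"].sum()),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
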