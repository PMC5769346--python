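"""Filtering and compositional normalization of per-domain OTU count tables.

Amplicon sequencing yields per-sample read counts for each OTU. Because the
library size of a sample is an arbitrary technical quantity, only the relative
abundances are informative: each sample is a composition on the simplex. The
pipeline here mirrors standard practice for compositionally robust network
inference: discard failed samples (too few reads), discard rare/artifact OTUs,
add a pseudocount, close to relative abundance (total-sum scaling), and apply
the centered log-ratio (CLR) transform per domain. CLR matrices from multiple
marker genes (e.g. 16S for bacteria, ITS for fungi) sequenced on the same
samples are then column-concatenated into a single cross-domain matrix, which
is the valid input to sparse inverse-covariance estimation: per-domain CLR
removes each domain's own closure effect, and, because the markers are
amplified separately, the domains never competed for reads, so no joint
closure exists to remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "CompositionMatrix",
    "ClrMatrix",
    "CrossDomainMatrix",
    "FilterReport",
    "filter_samples",
    "filter_otus",
    "to_composition",
    "clr_transform",
    "assemble_cross_domain",
    "naive_joint_clr",
]


class PreprocessError(ValueError):
    """Raised when a filtering or normalization step cannot proceed."""


@dataclass
class OtuTable:
    """A per-domain OTU count table: samples in rows, OTUs in columns.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = sample ids, columns = OTU ids.
    domain_label
        Marker-gene / domain tag, e.g. ``"16S"`` or ``"ITS"``.
    taxonomy
        Optional map OTU id -> lineage string (semicolon-delimited ranks,
        Greengenes ``k__...;p__...`` prefixes accepted).
    """

    counts: pd.DataFrame
    domain_label: str = ""
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise PreprocessError("OTU counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise PreprocessError("duplicate sample ids in count table")
        if self.counts.columns.has_duplicates:
            raise PreprocessError("duplicate OTU ids in count table")
        unknown = set(self.taxonomy) - set(map(str, self.counts.columns))
        if unknown:
            raise PreprocessError(
                f"taxonomy refers to unknown OTU ids: {sorted(unknown)[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.index]

    @property
    def otu_ids(self) -> list[str]:
        return [str(o) for o in self.counts.columns]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class CompositionMatrix:
    """Strictly positive relative abundances; every row sums to 1."""

    values: pd.DataFrame
    domain_label: str = ""

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if (arr <= 0).any():
            raise PreprocessError(
                "compositions must be strictly positive; apply a pseudocount "
                "before closure"
            )
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12):
            raise PreprocessError("composition rows must sum to 1")


@dataclass
class ClrMatrix:
    """Centered log-ratio coordinates; every row sums to 0."""

    values: pd.DataFrame
    source_domain: str = ""

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if arr.size and np.abs(arr.sum(axis=1)).max() > 1e-9:
            raise PreprocessError("CLR rows must sum to 0")


@dataclass
class CrossDomainMatrix:
    """Column-wise concatenation ``Z = [CLR(X) CLR(Y) ...]`` over shared samples.

    ``block_index`` maps each domain label to its ``(start, stop)`` column
    range (Python half-open convention).
    """

    values: pd.DataFrame
    block_index: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        stops = sorted(self.block_index.values())
        cursor = 0
        for start, stop in stops:
            if start != cursor:
                raise PreprocessError("block ranges must partition the columns")
            cursor = stop
        if cursor != self.values.shape[1]:
            raise PreprocessError("block ranges must cover all columns")

    @property
    def domains(self) -> list[str]:
        return list(self.block_index)

    def block(self, domain: str) -> pd.DataFrame:
        start, stop = self.block_index[domain]
        return self.values.iloc[:, start:stop]

    def column_domains(self) -> list[str]:
        out = [""] * self.values.shape[1]
        for dom, (start, stop) in self.block_index.items():
            for j in range(start, stop):
                out[j] = dom
        return out


@dataclass
class FilterReport:
    """Counts of entities dropped by each filtering rule."""

    n_dropped_prevalence: int = 0
    n_dropped_singleton: int = 0
    n_dropped_samples: int = 0


def filter_samples(table: OtuTable, min_reads: int) -> OtuTable:
    """Drop samples whose total read count is below ``min_reads``.

    "Fewer than" is strict: a sample with exactly ``min_reads`` reads passes.
    """
    if min_reads < 1:
        raise PreprocessError("min_reads must be >= 1")
    totals = table.sample_totals()
    keep = totals >= min_reads
    if not keep.any():
        raise PreprocessError(
            f"no samples pass the minimum read threshold ({min_reads} reads)"
        )
    return OtuTable(
        counts=table.counts.loc[keep],
        domain_label=table.domain_label,
        taxonomy=dict(table.taxonomy),
    )


def filter_otus(
    table: OtuTable,
    min_prevalence_fraction: float = 1.0 / 3.0,
    return_report: bool = False,
) -> OtuTable | tuple[OtuTable, FilterReport]:
    """Drop rare and artifact OTUs.

    Two rules, applied to the table as given (per input table, before any
    cross-domain sample intersection):

    1. *Prevalence*: an OTU must have a nonzero count in at least
       ``ceil(min_prevalence_fraction * n_samples)`` samples ("present in 1/3
       or more of the samples"); this damps the influence of repeated samples
       from a single host.
    2. *Singleton reads*: an OTU whose count is <= 1 in every sample where it
       occurs is treated as sequencing noise and removed even if prevalent.
    """
    if table.n_samples == 0 or table.n_otus == 0:
        raise PreprocessError("cannot filter an empty table")
    if not 0 < min_prevalence_fraction <= 1:
        raise PreprocessError("min_prevalence_fraction must be in (0, 1]")
    arr = table.counts.to_numpy()
    n = table.n_samples
    threshold = int(np.ceil(min_prevalence_fraction * n))
    prevalence = (arr > 0).sum(axis=0)
    prevalent = prevalence >= threshold
    max_count = arr.max(axis=0)
    not_singleton = max_count > 1
    keep = prevalent & not_singleton
    report = FilterReport(
        n_dropped_prevalence=int((~prevalent).sum()),
        n_dropped_singleton=int((prevalent & ~not_singleton).sum()),
    )
    if not keep.any():
        raise PreprocessError(
            "all OTUs removed by filtering (prevalence threshold "
            f"{threshold}/{n} samples and singleton-read rule)"
        )
    out = OtuTable(
        counts=table.counts.loc[:, keep],
        domain_label=table.domain_label,
        taxonomy={
            o: lin for o, lin in table.taxonomy.items()
            if o in set(table.counts.columns[keep].astype(str))
        },
    )
    return (out, report) if return_report else out


def to_composition(table: OtuTable, pseudocount: float = 1.0) -> CompositionMatrix:
    """Add a pseudocount to every cell and close each sample to sum 1.

    The pseudocount is applied before total-sum scaling so that zeros (OTUs
    absent from a sample) become small positive values and the log-ratio
    transform is defined everywhere.
    """
    if pseudocount <= 0:
        raise PreprocessError("pseudocount must be positive")
    arr = table.counts.to_numpy(float) + pseudocount
    arr = arr / arr.sum(axis=1, keepdims=True)
    return CompositionMatrix(
        values=pd.DataFrame(arr, index=table.counts.index, columns=table.counts.columns),
        domain_label=table.domain_label,
    )


def clr_transform(comp: CompositionMatrix) -> ClrMatrix:
    """Centered log-ratio transform, natural log, per sample.

    ``clr(x)_i = log(x_i / g(x))`` with ``g(x)`` the geometric mean of the
    row; equivalently ``log(x_i)`` minus the row mean of the logs. Rows of the
    result sum to zero. The transform is scale invariant: multiplying a row by
    any positive constant (e.g. undoing the closure) leaves it unchanged,
    which is what makes CLR covariance a usable proxy for the covariance of
    log absolute abundances.
    """
    arr = comp.values.to_numpy(float)
    if (arr <= 0).any():
        raise PreprocessError(
            "CLR requires strictly positive entries; add a pseudocount first"
        )
    logs = np.log(arr)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(
        values=pd.DataFrame(clr, index=comp.values.index, columns=comp.values.columns),
        source_domain=comp.domain_label,
    )


def assemble_cross_domain(
    clr_blocks: list[ClrMatrix],
    sample_id_map: dict[str, dict[str, str]] | None = None,
) -> CrossDomainMatrix:
    """Concatenate per-domain CLR matrices over their shared samples.

    Each block is restricted to the intersection of sample ids (a combined
    network uses only samples successfully sequenced in every domain), rows
    are aligned to the first block's sample order, and OTU ids are prefixed
    with their domain label so ids are globally unique. ``sample_id_map``
    optionally renames samples per domain (``{domain: {old: new}}``) before
    intersection, to reconcile run-specific naming.
    """
    if len(clr_blocks) < 2:
        raise PreprocessError("cross-domain assembly needs at least 2 domains")
    labels = [b.source_domain or f"domain{i}" for i, b in enumerate(clr_blocks)]
    if len(set(labels)) != len(labels):
        raise PreprocessError(f"domain labels must be unique, got {labels}")

    frames: list[pd.DataFrame] = []
    for label, block in zip(labels, clr_blocks):
        df = block.values.copy()
        if sample_id_map and label in sample_id_map:
            df.index = [sample_id_map[label].get(str(s), str(s)) for s in df.index]
        else:
            df.index = df.index.astype(str)
        frames.append(df)

    shared = frames[0].index
    for df in frames[1:]:
        shared = shared.intersection(df.index)
    if len(shared) == 0:
        raise PreprocessError("no samples shared across all domains")
    # keep the first block's sample order
    shared = [s for s in frames[0].index if s in set(shared)]
    if len(shared) == 1:
        warnings.warn(
            "only one shared sample across domains; covariance will be degenerate",
            UserWarning,
            stacklevel=2,
        )

    block_index: dict[str, tuple[int, int]] = {}
    pieces = []
    cursor = 0
    seen_cols: set[str] = set()
    for label, df in zip(labels, frames):
        piece = df.loc[shared]
        piece.columns = [f"{label}:{c}" for c in piece.columns]
        dup = seen_cols.intersection(piece.columns)
        if dup:
            raise PreprocessError(f"duplicate OTU ids after namespacing: {sorted(dup)[:5]}")
        seen_cols.update(piece.columns)
        block_index[label] = (cursor, cursor + piece.shape[1])
        cursor += piece.shape[1]
        pieces.append(piece)
    values = pd.concat(pieces, axis=1)
    return CrossDomainMatrix(values=values, block_index=block_index)


def naive_joint_clr(
    tables: list[OtuTable], pseudocount: float = 1.0
) -> CrossDomainMatrix:
    """The *invalid* single-composition treatment of multi-domain counts.

    Concatenates the raw count tables over shared samples, closes the joint
    rows to sum 1 and CLR-transforms across all domains at once — i.e. it
    pretends the domains were sequenced in one competing library. Because
    each marker gene is amplified separately, the cross-domain count ratio
    mixes the arbitrary per-domain library sizes and is not scale invariant,
    so this transform injects spurious cross-domain covariance. Provided only
    as the comparison baseline motivating the per-domain CLR assembly.
    """
    if len(tables) < 2:
        raise PreprocessError("need at least 2 domains")
    labels = [t.domain_label or f"domain{i}" for i, t in enumerate(tables)]
    frames = []
    for label, t in zip(labels, tables):
        df = t.counts.copy()
        df.index = df.index.astype(str)
        df.columns = [f"{label}:{c}" for c in df.columns]
        frames.append(df)
    shared = frames[0].index
    for df in frames[1:]:
        shared = shared.intersection(df.index)
    if len(shared) == 0:
        raise PreprocessError("no samples shared across all domains")
    shared = [s for s in frames[0].index if s in set(shared)]
    joint = pd.concat([df.loc[shared] for df in frames], axis=1)
    arr = joint.to_numpy(float) + pseudocount
    arr = arr / arr.sum(axis=1, keepdims=True)
    logs = np.log(arr)
    clr = logs - logs.mean(axis=1, keepdims=True)
    block_index: dict[str, tuple[int, int]] = {}
    cursor = 0
    for label, df in zip(labels, frames):
        block_index[label] = (cursor, cursor + df.shape[1])
        cursor += df.shape[1]
    return CrossDomainMatrix(
        values=pd.DataFrame(clr, index=shared, columns=joint.columns),
        block_index=block_index,
    )
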