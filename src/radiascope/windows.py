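"""Window-based locus selection, per-locus filters and data-type partitioning.

Mirrors the whole-genome-alignment bookkeeping used to assemble family-level
phylogenomic locus sets: within each ~10-kb alignment window the 1-kb
sub-span with the highest site-wise occupancy is chosen, fragmentary
sequences (under half the median ungapped length) are dropped, loci with
fewer than four sequences are rejected, and the surviving loci are
partitioned by annotation overlap into exon-overlapping, intron-overlapping
and purely intergenic classes (exon takes precedence, which is what makes
the published class counts additive).

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WindowBlock",
    "LocusRecord",
    "LocusSet",
    "FilterResult",
    "select_best_subwindow",
    "filter_locus",
    "partition_by_type",
    "combine_sets",
    "generate_window_fixture",
    "read_annotations",
]


@dataclass
class WindowBlock:
    """One alignment window with per-column occupancy (non-gap count)."""

    id: str
    chrom: str
    start: int
    end: int
    occupancy: np.ndarray
    sequences: dict[str, str] | None = None

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy)
        if self.end - self.start != len(self.occupancy):
            raise ValueError(f"window {self.id}: span does not match occupancy length")
        if self.sequences:
            lens = {len(s) for s in self.sequences.values()}
            if lens != {self.end - self.start}:
                raise ValueError(f"window {self.id}: ragged sequences")
            if int(self.occupancy.max(initial=0)) > len(self.sequences):
                raise ValueError(f"window {self.id}: occupancy exceeds sequence count")


@dataclass
class LocusRecord:
    """One selected locus with its category flags and per-sequence lengths."""

    id: str
    chrom: str
    start: int
    end: int
    n_sequences: int
    ungapped_lengths: dict[str, int] = field(default_factory=dict)
    exon_overlap: bool = False
    intron_overlap: bool = False
    uce: bool = False
    source_window: str | None = None
    sequences: dict[str, str] | None = None

    @property
    def purely_intergenic(self) -> bool:
        return not self.exon_overlap and not self.intron_overlap


@dataclass
class FilterResult:
    locus: LocusRecord | None
    kept: bool
    reason: str | None = None
    dropped: list[str] = field(default_factory=list)


@dataclass
class LocusSet:
    """Named id collection with category tallies (ids are unique)."""

    name: str
    ids: list[str]
    tallies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"locus set {self.name!r} has duplicate ids")

    @property
    def n(self) -> int:
        return len(self.ids)


def select_best_subwindow(
    block: WindowBlock,
    locus_len: int = 1000,
    search_span: int = 2000,
    stride: int = 1,
) -> LocusRecord:
    """The ``locus_len`` sub-span with maximal summed occupancy among the first
    ``search_span`` columns; ties go to the leftmost start."""
    width = block.end - block.start
    if width < locus_len:
        raise ValueError(f"window {block.id} shorter than locus length {locus_len}")
    span = min(search_span, width)
    if locus_len > span:
        raise ValueError("locus_len exceeds search_span")
    occ = np.asarray(block.occupancy[:span], dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(occ)])
    starts = np.arange(0, span - locus_len + 1, stride)
    sums = csum[starts + locus_len] - csum[starts]
    best = int(starts[int(np.argmax(sums))])  # argmax returns first max: leftmost

    seqs = None
    ungapped: dict[str, int] = {}
    if block.sequences is not None:
        seqs = {
            name: s[best : best + locus_len] for name, s in block.sequences.items()
        }
        seqs = {name: s for name, s in seqs.items() if set(s) != {"-"}}
        ungapped = {name: len(s) - s.count("-") for name, s in seqs.items()}
    return LocusRecord(
        id=f"{block.id}.locus",
        chrom=block.chrom,
        start=block.start + best,
        end=block.start + best + locus_len,
        n_sequences=len(seqs) if seqs is not None else int(block.occupancy[:span].max()),
        ungapped_lengths=ungapped,
        source_window=block.id,
        sequences=seqs,
    )


def filter_locus(
    locus: LocusRecord,
    min_frac_of_median: float = 0.5,
    min_sequences: int = 4,
) -> FilterResult:
    """Drop fragmentary sequences and reject sparse loci.

    The median ungapped length is computed once, over all sequences, before
    any removal; sequences strictly under ``min_frac_of_median`` of it are
    dropped (exactly-half survives); the locus is rejected when fewer than
    ``min_sequences`` remain. Rejection is a value, not an error.
    """
    lengths = locus.ungapped_lengths
    if not lengths:
        return FilterResult(None, False, reason="no sequences")
    med = float(np.median(list(lengths.values())))
    cutoff = min_frac_of_median * med
    dropped = [name for name, ln in lengths.items() if ln < cutoff]
    surviving = {name: ln for name, ln in lengths.items() if ln >= cutoff}
    if len(surviving) < min_sequences:
        return FilterResult(
            None, False, reason=f"fewer than {min_sequences} sequences", dropped=dropped
        )
    new = LocusRecord(
        id=locus.id,
        chrom=locus.chrom,
        start=locus.start,
        end=locus.end,
        n_sequences=len(surviving),
        ungapped_lengths=surviving,
        exon_overlap=locus.exon_overlap,
        intron_overlap=locus.intron_overlap,
        uce=locus.uce,
        source_window=locus.source_window,
        sequences=(
            {k: v for k, v in locus.sequences.items() if k in surviving}
            if locus.sequences is not None
            else None
        ),
    )
    return FilterResult(new, True, dropped=dropped)


def read_annotations(text: str) -> pd.DataFrame:
    """Parse a BED-like TSV (chrom, start, end, type) validating each line."""
    rows = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"annotation line {i}: expected 4 columns")
        chrom, start, end, kind = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if end <= start:
            raise ValueError(f"annotation line {i}: end <= start")
        rows.append({"chrom": chrom, "start": start, "end": end, "type": kind})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "type"])


class _IntervalLookup:
    """Per-chromosome sorted-start + prefix-max-end overlap queries."""

    def __init__(self, table: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if table.empty:
            return
        for chrom, sub in table.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            self.by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        if chrom not in self.by_chrom:
            return np.zeros(len(starts), dtype=bool)
        istarts, prefix_max_end = self.by_chrom[chrom]
        idx = np.searchsorted(istarts, ends, side="left") - 1
        out = np.zeros(len(starts), dtype=bool)
        has = idx >= 0
        out[has] = prefix_max_end[idx[has]] > starts[has]
        return out


def partition_by_type(
    loci: Sequence[LocusRecord], annotations: pd.DataFrame
) -> tuple[dict[str, int], dict[str, LocusSet]]:
    """Flag each locus by annotation overlap and partition into three classes.

    A locus intersecting any exon interval (>= 1 shared base) is
    exon-overlap; otherwise one intersecting any intron interval is
    intron-overlap; otherwise it is purely intergenic. Exon-over-intron
    precedence keeps the classes disjoint so their tallies are additive.
    A UCE flag is set independently of the three-way partition.
    """
    if not annotations.empty:
        bad = annotations[annotations["end"] <= annotations["start"]]
        if not bad.empty:
            raise ValueError(f"malformed interval at row {int(bad.index[0])}: end <= start")
    lookups = {
        kind: _IntervalLookup(
            annotations[annotations["type"] == kind] if not annotations.empty else annotations
        )
        for kind in ("exon", "intron", "uce")
    }

    groups: dict[str, list[str]] = {"exon": [], "intron": [], "intergenic": []}
    chroms: dict[str, list[int]] = {}
    for i, locus in enumerate(loci):
        chroms.setdefault(locus.chrom, []).append(i)
    for chrom, idxs in chroms.items():
        starts = np.array([loci[i].start for i in idxs])
        ends = np.array([loci[i].end for i in idxs])
        is_exon = lookups["exon"].overlaps(chrom, starts, ends)
        is_intron = lookups["intron"].overlaps(chrom, starts, ends)
        is_uce = lookups["uce"].overlaps(chrom, starts, ends)
        for j, i in enumerate(idxs):
            locus = loci[i]
            locus.uce = bool(is_uce[j])
            if is_exon[j]:
                locus.exon_overlap, locus.intron_overlap = True, False
                groups["exon"].append(locus.id)
            elif is_intron[j]:
                locus.exon_overlap, locus.intron_overlap = False, True
                groups["intron"].append(locus.id)
            else:
                locus.exon_overlap = locus.intron_overlap = False
                groups["intergenic"].append(locus.id)
    tallies = {k: len(v) for k, v in groups.items()}
    tallies["total"] = len(loci)
    sets = {
        k: LocusSet(name=k, ids=v, tallies={k: len(v)}) for k, v in groups.items()
    }
    return tallies, sets


def combine_sets(base: LocusSet, additions: Iterable[LocusSet]) -> LocusSet:
    """Disjoint union with exact tally bookkeeping; duplicate ids are an error."""
    ids = list(base.ids)
    seen = set(ids)
    tallies = dict(base.tallies)
    names = [base.name]
    for add in additions:
        for i in add.ids:
            if i in seen:
                raise ValueError(f"duplicate locus id across sets: {i!r}")
            seen.add(i)
        ids.extend(add.ids)
        for k, v in add.tallies.items():
            tallies[k] = tallies.get(k, 0) + v
        names.append(add.name)
    return LocusSet(name="+".join(names), ids=ids, tallies=tallies)


def generate_window_fixture(
    counts: Mapping[str, int],
    occupancy_profile: np.ndarray | None = None,
    seed: int | None = None,
    window_len: int = 10_000,
    locus_len: int = 1000,
    n_sequences: int = 8,
    with_sequences: bool = False,
) -> tuple[list[WindowBlock], pd.DataFrame]:
    """Synthetic window blocks plus annotations realizing requested category counts.

    ``counts`` maps category ("exon", "intron", "uce", "intergenic") to the
    number of windows whose selected locus will carry that overlap; the
    ``partition_by_type`` operation run on the output reproduces the counts
    exactly by construction. In metadata-only mode (``with_sequences=False``)
    the blocks carry only an occupancy profile, which is what the large
    published tallies need.
    """
    for k, v in counts.items():
        if k not in ("exon", "intron", "uce", "intergenic"):
            raise ValueError(f"unknown category {k!r}")
        if v < 0:
            raise ValueError(f"negative count for {k!r}")
    rng = np.random.default_rng(seed)
    if occupancy_profile is None:
        occupancy_profile = np.full(window_len, n_sequences, dtype=int)
    occupancy_profile = np.asarray(occupancy_profile)
    if len(occupancy_profile) != window_len:
        raise ValueError("occupancy profile length must equal window_len")

    blocks: list[WindowBlock] = []
    ann_rows = []
    pos = 0
    widx = 0
    order = [("exon", counts.get("exon", 0)), ("intron", counts.get("intron", 0)),
             ("uce", counts.get("uce", 0)), ("intergenic", counts.get("intergenic", 0))]
    alphabet = np.array(list("ACGT"))
    for kind, n in order:
        for _ in range(n):
            wid = f"w{widx:06d}"
            block = WindowBlock(
                id=wid,
                chrom="chrSyn",
                start=pos,
                end=pos + window_len,
                occupancy=occupancy_profile.copy(),
                sequences=None,
            )
            if with_sequences:
                seqs = {}
                for s in range(n_sequences):
                    row = alphabet[rng.integers(0, 4, size=window_len)]
                    gaps = occupancy_profile <= s
                    row[gaps] = "-"
                    seqs[f"sp{s + 1}"] = "".join(row)
                block.sequences = seqs
            blocks.append(block)
            if kind != "intergenic":
                # interval overlapping the first locus_len columns (where the
                # selected locus must start under a flat occupancy profile)
                ann_rows.append(
                    {
                        "chrom": "chrSyn",
                        "start": pos + locus_len // 4,
                        "end": pos + locus_len // 2,
                        "type": kind,
                    }
                )
            pos += window_len
            widx += 1
    annotations = pd.DataFrame(ann_rows, columns=["chrom", "start", "end", "type"])
    return blocks, annotations


def generate_locus_fixture(
    counts: Mapping[str, int],
    locus_len: int = 1000,
    window_len: int = 10_000,
    n_sequences: int = 8,
) -> tuple[list[LocusRecord], pd.DataFrame]:
    """Metadata-only fixture at published-tally scale: bare locus records plus
    annotation intervals such that :func:`partition_by_type` reproduces the
    requested category counts exactly. No occupancy or sequence payload, so
    tallies in the hundreds of thousands stay cheap."""
    for k, v in counts.items():
        if k not in ("exon", "intron", "uce", "intergenic"):
            raise ValueError(f"unknown category {k!r}")
        if v < 0:
            raise ValueError(f"negative count for {k!r}")
    loci: list[LocusRecord] = []
    ann_rows = []
    pos = 0
    widx = 0
    for kind in ("exon", "intron", "uce", "intergenic"):
        for _ in range(counts.get(kind, 0)):
            lid = f"L{widx:06d}"
            loci.append(
                LocusRecord(
                    id=lid,
                    chrom="chrSyn",
                    start=pos,
                    end=pos + locus_len,
                    n_sequences=n_sequences,
                    source_window=f"w{widx:06d}",
                )
            )
            if kind != "intergenic":
                ann_rows.append(
                    {
                        "chrom": "chrSyn",
                        "start": pos + locus_len // 4,
                        "end": pos + locus_len // 2,
                        "type": kind,
                    }
                )
            pos += window_len
            widx += 1
    annotations = pd.DataFrame(ann_rows, columns=["chrom", "start", "end", "type"])
    return loci, annotations
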