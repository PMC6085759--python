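"""Read simulation at TPM-proportional depth and splice-aware compatibility.

Alignment is replaced by an exact oracle: a read simulated from its origin
isoform is *compatible* with a candidate isoform iff the read's genomic
footprint — every projected genomic segment of every mate, including the exact
splice junctions it crosses — occurs as a contiguous window of the candidate's
spliced sequence of genomic positions.  Mates of a pair may straddle any
candidate-internal gap between them.  No sequencing errors, soft clipping or
positional biases are modelled: the simulation isolates the coverage-window /
depth limits under study.

Two code paths produce equivalence classes:

* an explicit per-read path (:func:`simulate_reads`, :func:`compatible`,
  :func:`build_equivalence_classes`) used for small-scale work and debugging;
* a vectorised path (:func:`simulate_equivalence_classes`) that enumerates,
  for each (origin, candidate) pair, the compatible read start positions and
  tallies multinomially sampled reads directly into classes.  Both implement
  the same compatibility semantics (tested against each other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .expression import ExpressionProfile
from .protocols import LibraryProtocol, trim_transcript
from .transcriptome import Gene, Isoform, Transcriptome

__all__ = [
    "SimulatedRead",
    "EquivalenceClassTable",
    "expected_counts",
    "simulate_reads",
    "projection_index",
    "compatible",
    "build_equivalence_classes",
    "simulate_equivalence_classes",
    "write_reads_tsv",
    "write_classes_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated read: one or two intervals in origin-transcript coordinates."""

    read_id: str
    origin_isoform_id: str
    mates: tuple[tuple[int, int], ...]  # ((a1,b1),) or ((a1,b1),(a2,b2))

    def __post_init__(self) -> None:
        for a, b in self.mates:
            if not 0 <= a < b:
                raise ValueError(f"bad mate interval [{a}, {b})")
        if len(self.mates) == 2 and self.mates[0][0] > self.mates[1][0]:
            raise ValueError("mate1 must precede mate2 within the fragment")


@dataclass
class EquivalenceClassTable:
    """Read counts grouped by compatibility set (sorted isoform-id tuples)."""

    classes: dict[tuple[str, ...], int] = field(default_factory=dict)
    total_reads: int = 0
    unassigned: int = 0

    def add(self, members: tuple[str, ...], count: int = 1) -> None:
        if count <= 0:
            return
        self.classes[members] = self.classes.get(members, 0) + count
        self.total_reads += count

    def merge(self, other: "EquivalenceClassTable") -> None:
        for members, count in other.classes.items():
            self.classes[members] = self.classes.get(members, 0) + count
        self.total_reads += other.total_reads
        self.unassigned += other.unassigned

    def by_gene(self, tx: Transcriptome) -> dict[str, "EquivalenceClassTable"]:
        """Split into per-gene tables (classes never span genes)."""
        out: dict[str, EquivalenceClassTable] = {}
        for members, count in self.classes.items():
            gid = tx.gene_of(members[0]).gene_id
            out.setdefault(gid, EquivalenceClassTable()).add(members, count)
        return out


# ---------------------------------------------------------------------------
# Depth allocation
# ---------------------------------------------------------------------------


def expected_counts(
    profile: ExpressionProfile, total_reads: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial per-isoform read counts at TPM-proportional depth.

    Counts are aligned with ``profile.isoform_ids`` and sum exactly to
    ``total_reads`` (multinomial rather than independent Poisson allocation
    keeps the read budget exact).
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    p = np.asarray(profile.tpm, dtype=float)
    return rng.multinomial(int(total_reads), p / p.sum())


# ---------------------------------------------------------------------------
# Per-read simulation
# ---------------------------------------------------------------------------


def _sample_fragments(
    n: int, template_len: int, protocol: LibraryProtocol, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment lengths and start offsets (within the template) for n reads."""
    R = protocol.read_length
    if protocol.paired and template_len > R:
        frag = np.rint(
            rng.normal(protocol.fragment_mean, protocol.fragment_sd, size=n)
        ).astype(int)
        frag = np.clip(frag, R, template_len)
    else:
        # single-end, or a template too short for even one full read
        frag = np.full(n, min(R, template_len), dtype=int)
    starts = rng.integers(0, template_len - frag + 1)
    return frag, starts


def simulate_reads(
    templates: Mapping[str, tuple[int, int]],
    counts: Mapping[str, int],
    protocol: LibraryProtocol,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    """Simulate reads with uniform fragment starts over each covered template.

    ``templates`` maps isoform_id → covered interval [a, b) in transcript
    coordinates; ``counts`` maps isoform_id → number of reads.  Fragments
    longer than the template are clipped to it; a template shorter than the
    read length yields single reads covering the whole template.
    """
    reads: list[SimulatedRead] = []
    R = protocol.read_length
    clip_logged = False
    for iso_id, count in counts.items():
        if count <= 0:
            continue
        t0, t1 = templates[iso_id]
        tlen = t1 - t0
        if tlen < R and not clip_logged:
            logger.info(
                "%s: template (%d nt) shorter than read length (%d); reads cover "
                "the whole template", iso_id, tlen, R,
            )
            clip_logged = True
        frag, starts = _sample_fragments(int(count), tlen, protocol, rng)
        for k in range(int(count)):
            s = t0 + int(starts[k])
            f = int(frag[k])
            if protocol.paired and tlen > R:
                mates = ((s, s + R), (s + f - R, s + f))
            else:
                mates = ((s, s + f),)
            reads.append(
                SimulatedRead(f"{iso_id}:r{k}", iso_id, mates)
            )
    return reads


# ---------------------------------------------------------------------------
# Splice-aware compatibility
# ---------------------------------------------------------------------------


def projection_index(origin: Isoform, candidate: Isoform) -> np.ndarray:
    """For each origin transcript coordinate t, the candidate transcript
    coordinate of the same genomic base, or -1 where the base is absent from
    the candidate.  Both isoforms must be on the same strand (same gene).
    """
    L = origin.length
    f = np.full(L, -1, dtype=np.int64)
    strand = origin.strand

    def offsets(iso: Isoform) -> list[tuple[object, int]]:
        out, off = [], 0
        for ex in iso.transcript_order():
            out.append((ex, off))
            off += ex.length
        return out

    for oex, o0 in offsets(origin):
        for cex, c0 in offsets(candidate):
            a = max(oex.start, cex.start)
            b = min(oex.end, cex.end)
            if a >= b:
                continue
            if strand == "+":
                t0 = o0 + (a - oex.start)
                f[t0:t0 + (b - a)] = (c0 + a - cex.start) + np.arange(b - a)
            else:
                t0 = o0 + (oex.end - b)
                f[t0:t0 + (b - a)] = (c0 + cex.end - b) + np.arange(b - a)
    return f


def _interval_ok(f: np.ndarray, a: int, b: int) -> bool:
    """True iff origin window [a,b) maps to a contiguous candidate window."""
    seg = f[a:b]
    if np.any(seg < 0):
        return False
    return bool(np.all(np.diff(seg) == 1))


def compatible(
    read: SimulatedRead, candidate: Isoform, tx: Transcriptome
) -> bool:
    """Exact splice-aware compatibility of ``read`` with ``candidate``.

    True iff every projected genomic segment of every mate is contained in the
    candidate's exon chain and every splice junction implied by a mate matches
    a candidate junction exactly.  The gap between mates may straddle
    candidate-internal junctions freely.
    """
    origin = tx.isoform(read.origin_isoform_id)
    if candidate.gene_id != origin.gene_id:
        return False  # genes never overlap by construction
    f = projection_index(origin, candidate)
    return all(_interval_ok(f, a, b) for a, b in read.mates)


def build_equivalence_classes(
    reads: Iterable[SimulatedRead], tx: Transcriptome
) -> EquivalenceClassTable:
    """Group reads by their compatibility set over the origin's gene.

    Every read must be compatible with its own origin; a violation indicates a
    projection bug and raises ``RuntimeError``.
    """
    table = EquivalenceClassTable()
    cache: dict[tuple[str, tuple], tuple[str, ...]] = {}
    for read in reads:
        key = (read.origin_isoform_id, read.mates)
        members = cache.get(key)
        if members is None:
            gene = tx.gene_of(read.origin_isoform_id)
            members = tuple(
                sorted(
                    iso.isoform_id
                    for iso in gene.isoforms
                    if compatible(read, iso, tx)
                )
            )
            if read.origin_isoform_id not in members:
                raise RuntimeError(
                    f"read {read.read_id} incompatible with its origin "
                    f"{read.origin_isoform_id} (projection bug)"
                )
            cache[key] = members
        table.add(members)
    return table


# ---------------------------------------------------------------------------
# Vectorised equivalence-class simulation
# ---------------------------------------------------------------------------


def _start_masks(gene: Gene, read_len: int) -> dict[str, np.ndarray]:
    """Per origin isoform, a boolean matrix M[c, s]: read [s, s+read_len) on
    the origin is compatible with candidate c (candidates in id order).
    Start positions s run over [0, origin_length - read_len]."""
    masks: dict[str, np.ndarray] = {}
    isoforms = gene.isoforms
    for origin in isoforms:
        L = origin.length
        R = min(read_len, L)
        n_start = L - R + 1
        mat = np.empty((len(isoforms), n_start), dtype=bool)
        for ci, cand in enumerate(isoforms):
            if cand.isoform_id == origin.isoform_id:
                mat[ci] = True
                continue
            f = projection_index(origin, cand)
            bad = np.concatenate(([0], np.cumsum(f < 0)))
            jump = np.concatenate(([0], np.cumsum(np.diff(f) != 1)))
            s = np.arange(n_start)
            mat[ci] = (bad[s + R] - bad[s] == 0) & (jump[s + R - 1] - jump[s] == 0)
        masks[origin.isoform_id] = mat
    return masks


def _gene_class_counts(
    gene: Gene,
    counts: Mapping[str, int],
    protocol: LibraryProtocol,
    rng: np.random.Generator,
) -> EquivalenceClassTable:
    """Fast path: class counts for one gene under one protocol."""
    table = EquivalenceClassTable()
    ids = [iso.isoform_id for iso in gene.isoforms]
    if len(ids) == 1:
        table.add((ids[0],), int(counts.get(ids[0], 0)))
        return table

    R = protocol.read_length
    mask_cache: dict[int, dict[str, np.ndarray]] = {}

    def masks_for(read_len: int) -> dict[str, np.ndarray]:
        if read_len not in mask_cache:
            mask_cache[read_len] = _start_masks(gene, read_len)
        return mask_cache[read_len]

    for oi, origin in enumerate(gene.isoforms):
        n = int(counts.get(origin.isoform_id, 0))
        if n <= 0:
            continue
        t0, t1 = trim_transcript(origin.length, protocol)
        tlen = t1 - t0
        frag, starts = _sample_fragments(n, tlen, protocol, rng)
        s = t0 + starts
        Reff = min(R, tlen)
        if protocol.paired and tlen > R:
            mat = masks_for(R)[origin.isoform_id]
            comp = mat[:, s] & mat[:, s + frag - R]
        else:
            mat = masks_for(Reff)[origin.isoform_id]
            comp = mat[:, s]
        if not comp[oi].all():
            raise RuntimeError(
                f"{origin.isoform_id}: simulated read incompatible with its "
                "origin (projection bug)"
            )
        bits = 1 << np.arange(len(ids), dtype=np.int64)
        codes = (comp.astype(np.int64) * bits[:, None]).sum(axis=0)
        hist = np.bincount(codes, minlength=1)
        for code in np.nonzero(hist)[0]:
            members = tuple(ids[j] for j in range(len(ids)) if code >> j & 1)
            table.add(members, int(hist[code]))
    return table


def simulate_equivalence_classes(
    tx: Transcriptome,
    counts: Mapping[str, int] | np.ndarray,
    protocol: LibraryProtocol,
    rng: np.random.Generator,
) -> dict[str, EquivalenceClassTable]:
    """Simulate all reads for one protocol run, returning per-gene class tables.

    ``counts`` is either a mapping isoform_id → reads or an array aligned with
    ``tx.isoform_ids()`` (the output of :func:`expected_counts`).
    """
    if isinstance(counts, np.ndarray):
        counts = dict(zip(tx.isoform_ids(), counts.tolist()))
    out: dict[str, EquivalenceClassTable] = {}
    for gene in tx.genes:
        if any(counts.get(i.isoform_id, 0) > 0 for i in gene.isoforms):
            out[gene.gene_id] = _gene_class_counts(gene, counts, protocol, rng)
    return out


# ---------------------------------------------------------------------------
# Debug exports
# ---------------------------------------------------------------------------


def write_reads_tsv(reads: Iterable[SimulatedRead], path) -> None:
    """Coordinate table of simulated reads (transcript coordinates)."""
    with open(path, "w") as fh:
        fh.write("read_id\torigin_isoform_id\tmate\tstart\tend\n")
        for read in reads:
            for m, (a, b) in enumerate(read.mates, start=1):
                fh.write(f"{read.read_id}\t{read.origin_isoform_id}\t{m}\t{a}\t{b}\n")


def write_classes_tsv(table: EquivalenceClassTable, path) -> None:
    """Equivalence classes as comma-joined member lists with counts."""
    with open(path, "w") as fh:
        fh.write("members\tcount\n")
        for members in sorted(table.classes):
            fh.write(f"{','.join(members)}\t{table.classes[members]}\n")
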