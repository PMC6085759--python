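"""Synthetic multi-isoform transcriptome generator.

A transcriptome is a set of non-overlapping gene loci on a synthetic genome.
Each gene carries a *reference* isoform (all exons, full UTRs) and, for
multi-isoform genes (MIGs), additional isoforms derived from the reference by
exactly one alternative-transcription/splicing event: exon skipping, intron
retention, alternative 5'/3' splice site, alternative transcription start site
(TSS) or termination site (TTS).

Coordinates are 0-based half-open internally and strand-aware throughout:
"5' end" always means the transcript's 5' end, which on the minus strand is
the genomically rightmost exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .exceptions import ConfigurationError, EventNotApplicable

__all__ = [
    "Exon",
    "Isoform",
    "Gene",
    "Transcriptome",
    "AS_EVENTS",
    "derive_alternative_isoform",
    "generate_transcriptome",
    "validate_transcriptome",
]

logger = logging.getLogger(__name__)

#: Recognised alternative-isoform event tags.
AS_EVENTS = ("exon_skip", "intron_retention", "alt5ss", "alt3ss", "altTSS", "altTTS")

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Exon:
    """A genomic exon interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon start must precede end: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Isoform:
    """An isoform as an ordered (genomic) chain of non-overlapping exons."""

    isoform_id: str
    gene_id: str
    exons: tuple[Exon, ...]
    event_labels: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("isoform needs at least one exon")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.isoform_id}: exons must be sorted and non-overlapping"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        """Transcript length in nt (sum of exon lengths)."""
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span [start, end) of the isoform."""
        return self.exons[0].start, self.exons[-1].end

    def transcript_order(self) -> tuple[Exon, ...]:
        """Exons in 5'→3' transcript order (reversed genomic order on '-')."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def chain_key(self) -> tuple:
        """Hashable structural identity (used for collision detection)."""
        return tuple((e.start, e.end) for e in self.exons)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    isoforms: tuple[Isoform, ...]

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError("gene needs at least one isoform")

    @property
    def is_mig(self) -> bool:
        return len(self.isoforms) >= 2

    @property
    def reference(self) -> Isoform:
        """The reference isoform: all exons, no events."""
        return self.isoforms[0]


@dataclass
class Transcriptome:
    """Genes plus the synthetic genome they live on."""

    genes: tuple[Gene, ...]
    genome: Mapping[str, bytes]
    provenance: dict = field(default_factory=dict)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_isoforms(self) -> int:
        return sum(len(g.isoforms) for g in self.genes)

    @property
    def migs(self) -> tuple[Gene, ...]:
        return tuple(g for g in self.genes if g.is_mig)

    def isoforms(self) -> Iterator[Isoform]:
        for gene in self.genes:
            yield from gene.isoforms

    def isoform_ids(self) -> list[str]:
        """All isoform ids, grouped by gene, id-sorted within each gene."""
        return [i.isoform_id for i in self.isoforms()]

    def gene_of(self, isoform_id: str) -> Gene:
        try:
            return self._by_isoform[isoform_id]
        except AttributeError:
            self._by_isoform = {
                i.isoform_id: g for g in self.genes for i in g.isoforms
            }
            return self._by_isoform[isoform_id]

    def isoform(self, isoform_id: str) -> Isoform:
        gene = self.gene_of(isoform_id)
        for iso in gene.isoforms:
            if iso.isoform_id == isoform_id:
                return iso
        raise KeyError(isoform_id)


# ---------------------------------------------------------------------------
# Alternative-isoform derivation
# ---------------------------------------------------------------------------

_MIN_EXON_REMNANT = 20  # nt left of an exon after a splice-site shift


def derive_alternative_isoform(
    reference: Isoform,
    event: str,
    rng: np.random.Generator,
    *,
    min_utr: int = 20,
    min_shift: int = 10,
    index: int | None = None,
    shift: int | None = None,
    new_id: str | None = None,
) -> Isoform:
    """Derive an isoform differing from ``reference`` by exactly one event.

    Parameters
    ----------
    reference
        The gene's reference isoform (all exons).
    event
        One of :data:`AS_EVENTS`.
    rng
        Source of randomness for the exon/junction choice and shift size.
    min_utr
        Minimal length of the terminal exon remnant after an altTSS/altTTS trim.
    min_shift
        Minimal size (nt) of any boundary shift or trim.
    index, shift
        Optional deterministic overrides for the exon/junction index
        (transcript order where relevant) and the shift size.

    Raises
    ------
    EventNotApplicable
        If the reference's structure cannot host the event (e.g. exon skipping
        with no internal exon); callers should resample another event type.
    """
    if event not in AS_EVENTS:
        raise ConfigurationError(f"unknown AS event {event!r}")
    exons = list(reference.exons)  # genomic order
    n = len(exons)
    strand = reference.strand
    torder = list(range(n)) if strand == "+" else list(range(n - 1, -1, -1))

    def pick(lo: int, hi: int) -> int:  # inclusive bounds
        if index is not None:
            if not lo <= index <= hi:
                raise EventNotApplicable(f"{event}: index {index} out of [{lo},{hi}]")
            return index
        return int(rng.integers(lo, hi + 1))

    def pick_shift(max_d: int) -> int:
        if max_d < min_shift:
            raise EventNotApplicable(f"{event}: no room for a >= {min_shift} nt shift")
        if shift is not None:
            if not min_shift <= shift <= max_d:
                raise EventNotApplicable(f"{event}: shift {shift} out of range")
            return shift
        return int(rng.integers(min_shift, max_d + 1))

    if event == "exon_skip":
        if n < 3:
            raise EventNotApplicable("exon_skip needs an internal exon")
        k = pick(1, n - 2)
        new_exons = exons[:k] + exons[k + 1 :]

    elif event == "intron_retention":
        if n < 2:
            raise EventNotApplicable("intron_retention needs an intron")
        k = pick(0, n - 2)  # genomic index of the upstream exon of the intron
        merged = replace(exons[k], end=exons[k + 1].end)
        new_exons = exons[:k] + [merged] + exons[k + 2 :]

    elif event in ("alt5ss", "alt3ss"):
        if n < 2:
            raise EventNotApplicable(f"{event} needs a splice junction")
        j = pick(0, n - 2)  # junction index in transcript order
        # donor exon: transcript exon j (its 3' boundary); acceptor: exon j+1
        t_idx = torder[j] if event == "alt5ss" else torder[j + 1]
        ex = exons[t_idx]
        # the shifted boundary faces the intron between transcript exons j, j+1
        up, dn = sorted((torder[j], torder[j + 1]))
        intron_len = exons[dn].start - exons[up].end
        donor_side_is_end = (event == "alt5ss") == (strand == "+")
        mode = (
            ("extend", "shrink")[int(rng.integers(0, 2))]
            if intron_len - min_shift >= min_shift
            else "shrink"
        )
        if mode == "extend":
            d = pick_shift(intron_len - min_shift)  # keep a real intron
            d = -d
        else:
            d = pick_shift(ex.length - _MIN_EXON_REMNANT)
        if donor_side_is_end:
            new_ex = replace(ex, end=ex.end - d)
        else:
            new_ex = replace(ex, start=ex.start + d)
        new_exons = exons[:]
        new_exons[t_idx] = new_ex

    elif event in ("altTSS", "altTTS"):
        # trim the transcript terminus within its terminal exon
        at_5prime = event == "altTSS"
        t_idx = torder[0] if at_5prime else torder[-1]
        ex = exons[t_idx]
        d = pick_shift(ex.length - min_utr)
        trim_start = at_5prime == (strand == "+")
        new_ex = replace(ex, start=ex.start + d) if trim_start else replace(ex, end=ex.end - d)
        new_exons = exons[:]
        new_exons[t_idx] = new_ex

    return Isoform(
        isoform_id=new_id or f"{reference.isoform_id}:{event}",
        gene_id=reference.gene_id,
        exons=tuple(new_exons),
        event_labels=frozenset({event}),
    )


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def _sample_lengths(
    rng: np.random.Generator, n: int, log_mean: float, log_sd: float, lo: int, hi: int
) -> np.ndarray:
    x = np.exp(rng.normal(log_mean, log_sd, size=n))
    return np.clip(np.rint(x).astype(int), lo, hi)


def _truncated_geometric(rng: np.random.Generator, p: float, kmax: int) -> int:
    """Draw from {1..kmax} with P(k) ∝ (1-p)^(k-1)."""
    k = np.arange(1, kmax + 1)
    w = (1.0 - p) ** (k - 1)
    return int(rng.choice(k, p=w / w.sum()))


def generate_transcriptome(config, seed: int) -> Transcriptome:
    """Generate a synthetic transcriptome per ``config`` (see ``config.py``).

    The number of MIGs is exactly ``round(n_genes * mig_fraction)``; each MIG's
    isoform count is 1 + a truncated-geometric draw; every alternative isoform
    is derived from the gene's reference by a single event sampled from the
    configured event-type probabilities.  Fully reproducible for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_genes = config.n_genes
    n_mig = round(n_genes * config.mig_fraction)
    mig_flags = np.zeros(n_genes, dtype=bool)
    mig_flags[rng.choice(n_genes, size=n_mig, replace=False)] = True

    event_types = list(config.event_probs)
    event_p = np.array([config.event_probs[e] for e in event_types], dtype=float)
    event_p = event_p / event_p.sum()

    chrom = config.chrom_name
    cursor = config.intergene_gap
    genes: list[Gene] = []
    for gi in range(n_genes):
        gene_id = f"G{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = 2 + int(rng.poisson(config.exon_count_mean_extra))
        exon_lens = _sample_lengths(
            rng, n_exons, config.exon_len_log_mean, config.exon_len_log_sd,
            config.min_exon_len, config.max_exon_len,
        )
        intron_lens = _sample_lengths(
            rng, n_exons - 1, config.intron_len_log_mean, config.intron_len_log_sd,
            config.min_intron_len, config.max_intron_len,
        )
        exons = []
        pos = cursor
        for k in range(n_exons):
            exons.append(Exon(chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        cursor = pos + config.intergene_gap

        reference = Isoform(f"{gene_id}.I01", gene_id, tuple(exons))
        isoforms = [reference]
        if mig_flags[gi]:
            target = 1 + _truncated_geometric(
                rng, config.isoform_geom_p, config.max_isoforms - 1
            )
            seen = {reference.chain_key()}
            for extra in range(target - 1):
                iso = None
                for _ in range(20):
                    event = event_types[int(rng.choice(len(event_types), p=event_p))]
                    try:
                        cand = derive_alternative_isoform(
                            reference, event, rng,
                            min_utr=config.min_utr, min_shift=config.min_shift,
                            new_id=f"{gene_id}.I{len(isoforms) + 1:02d}",
                        )
                    except EventNotApplicable:
                        continue
                    if cand.chain_key() not in seen:
                        iso = cand
                        break
                if iso is None:
                    logger.info(
                        "%s: could not derive a distinct isoform; reducing "
                        "isoform count from %d to %d", gene_id, target, len(isoforms)
                    )
                    break
                seen.add(iso.chain_key())
                isoforms.append(iso)
        genes.append(Gene(gene_id, tuple(isoforms)))

    seq = _NUC[rng.integers(0, 4, size=cursor)].tobytes()
    provenance = {"seed": int(seed), "config": config.to_dict()}
    return Transcriptome(tuple(genes), {chrom: seq}, provenance)


def validate_transcriptome(tx: Transcriptome) -> None:
    """Assert all structural invariants; raises ``AssertionError`` on failure."""
    seen_ids: set[str] = set()
    prev_end: dict[str, int] = {}
    for gene in tx.genes:
        ref = gene.reference
        assert gene.is_mig == (len(gene.isoforms) >= 2)
        gstart, gend = ref.span
        assert gstart >= prev_end.get(ref.chrom, 0), f"{gene.gene_id}: gene overlap"
        prev_end[ref.chrom] = max(prev_end.get(ref.chrom, 0), gend)
        for iso in gene.isoforms:
            assert iso.isoform_id not in seen_ids, f"duplicate id {iso.isoform_id}"
            seen_ids.add(iso.isoform_id)
            assert iso.length == sum(e.length for e in iso.exons)
            assert iso.strand == ref.strand and iso.chrom == ref.chrom
            for a, b in zip(iso.exons, iso.exons[1:]):
                assert a.end <= b.start, f"{iso.isoform_id}: unsorted/overlapping exons"
            s, e = iso.span
            assert 0 <= s < e <= len(tx.genome[iso.chrom]), (
                f"{iso.isoform_id}: exon outside chromosome bounds"
            )
            # every isoform shares genomic bases with the reference
            shared = any(
                max(a.start, b.start) < min(a.end, b.end)
                for a in iso.exons for b in ref.exons
            )
            assert shared, f"{iso.isoform_id}: no overlap with reference"
            if iso is not ref:
                assert iso.event_labels, f"{iso.isoform_id}: missing event label"
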