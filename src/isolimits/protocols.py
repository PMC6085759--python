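"""Library-preparation strategies as transcript-coordinate coverage templates.

A UMI-tagged library sequences only a fixed window at the transcript's 3' (or
5') end; Smart-based (full-length cDNA) libraries and long-read sequencing
cover the whole transcript.  Windows are fixed per protocol — covered lengths
do not vary from transcript to transcript and no UMI deduplication is
modelled, deliberately mirroring the idealised simulation design.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigurationError

__all__ = [
    "LibraryProtocol",
    "read_spec_for_window",
    "trim_transcript",
    "effective_length",
    "umi3",
    "umi5",
    "smart",
    "longread",
]

#: window (nt or "full") → (read_length, paired)
READ_SPECS: dict[object, tuple[int, bool]] = {
    100: (25, False),
    200: (25, False),
    300: (50, False),
    500: (50, False),
    1000: (100, False),
    "full": (250, True),
}


def read_spec_for_window(window) -> tuple[int, bool]:
    """Read length and pairedness for a coverage window.

    Reads lengthen with the window so coverage stays even: 100/200 nt windows
    use 25 nt single-end reads, 300/500 use 50 nt, 1000 uses 100 nt, and
    full-length templates use 250 nt paired-end reads.
    """
    try:
        return READ_SPECS[window]
    except KeyError:
        raise ConfigurationError(
            f"no read spec for window {window!r}; custom windows must supply "
            "read_length/paired explicitly"
        ) from None


@dataclass(frozen=True)
class LibraryProtocol:
    """One library strategy: UMI3/UMI5 window, SMART full-length, or LONGREAD."""

    kind: str  # UMI3 | UMI5 | SMART | LONGREAD
    window: int | None = None
    read_length: int | None = None
    paired: bool = False
    fragment_mean: float | None = None
    fragment_sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("UMI3", "UMI5", "SMART", "LONGREAD"):
            raise ConfigurationError(f"unknown protocol kind {self.kind!r}")
        if self.kind in ("UMI3", "UMI5"):
            if self.window is None or self.window <= 0:
                raise ConfigurationError("UMI protocols need a positive window")
            if self.read_length is None or self.read_length <= 0:
                raise ConfigurationError("UMI protocols need a read length")
        if self.kind == "SMART" and (self.read_length is None or self.read_length <= 0):
            raise ConfigurationError("SMART needs a read length")
        if self.kind == "LONGREAD" and self.read_length is not None:
            raise ConfigurationError("LONGREAD has no read length (1 read = 1 transcript)")
        if self.paired and not self.fragment_mean:
            raise ConfigurationError("paired protocols need a fragment_mean")

    @property
    def name(self) -> str:
        if self.kind in ("UMI3", "UMI5"):
            return f"{self.kind.lower()}_{self.window}"
        return self.kind.lower()

    @property
    def mean_fragment(self) -> float:
        """Expected fragment length (read length for single-end)."""
        if self.kind == "LONGREAD":
            raise ConfigurationError("LONGREAD has no fragment model")
        return float(self.fragment_mean if self.paired else self.read_length)


def umi3(window: int) -> LibraryProtocol:
    rl, paired = read_spec_for_window(window)
    return LibraryProtocol("UMI3", window=window, read_length=rl, paired=paired)


def umi5(window: int) -> LibraryProtocol:
    rl, paired = read_spec_for_window(window)
    return LibraryProtocol("UMI5", window=window, read_length=rl, paired=paired)


def smart(fragment_mean: float = 350.0, fragment_sd: float = 35.0) -> LibraryProtocol:
    rl, paired = read_spec_for_window("full")
    return LibraryProtocol(
        "SMART", read_length=rl, paired=paired,
        fragment_mean=fragment_mean, fragment_sd=fragment_sd,
    )


def longread() -> LibraryProtocol:
    return LibraryProtocol("LONGREAD")


def trim_transcript(isoform_length: int, protocol: LibraryProtocol) -> tuple[int, int]:
    """Covered template interval [a, b) in transcript coordinates (5'→3').

    UMI3 keeps the terminal ``window`` nt at the 3' end, UMI5 the first
    ``window`` nt; SMART and LONGREAD cover the full transcript.  Transcripts
    shorter than the window are covered completely.
    """
    if isoform_length < 1:
        raise ValueError("isoform_length must be >= 1")
    if protocol.kind == "UMI3":
        return max(0, isoform_length - protocol.window), isoform_length
    if protocol.kind == "UMI5":
        return 0, min(protocol.window, isoform_length)
    return 0, isoform_length


def effective_length(template_length: int, protocol: LibraryProtocol) -> int:
    """Number of valid fragment placements: len − mean fragment + 1, floor 1."""
    return max(1, template_length - int(round(protocol.mean_fragment)) + 1)
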