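"""Voss indicator encoding and power-spectral-density computation.

A DNA string of length L becomes four binary channels (order A, G, C, T);
each channel is zero-padded to a common length ``n`` and transformed with
the unnormalized DFT, and the squared magnitudes of the four transforms
are summed into a single nonnegative spectrum of length ``n``.  The full
two-sided spectrum is kept.  Ambiguous IUPAC codes contribute zero to
every channel.

Conventions fixed here (the source method leaves them open): the spectrum
is two-sided and unnormalized; the DC bin is retained by default but can
be zeroed with ``drop_dc`` since it encodes only base composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from spectraclust.sequence_io import DnaSequence, UNAMBIGUOUS

logger = logging.getLogger(__name__)

#: Channel order of the indicator matrix.
CHANNELS = ("A", "G", "C", "T")


@dataclass(frozen=True)
class VossSignal:
    """4 x L binary indicator matrix for one sequence.

    Row ``c`` holds a 1 exactly where base ``CHANNELS[c]`` occurs.
    Ambiguous positions are zero in all four rows, so the per-position
    column sum is 1 for unambiguous bases and 0 otherwise.
    """

    indicators: np.ndarray
    source_id: str
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.indicators, dtype=np.uint8)
        if arr.ndim != 2 or arr.shape[0] != 4:
            raise ValueError(f"indicator matrix must be 4 x L, got shape {arr.shape}")
        object.__setattr__(self, "indicators", arr)

    @property
    def length(self) -> int:
        return self.indicators.shape[1]


@dataclass(frozen=True)
class PowerSpectrum:
    """Length-``n`` nonnegative spectral vector tied to a sequence id."""

    values: np.ndarray
    source_id: str
    n: int
    orig_length: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.n,):
            raise ValueError(f"spectrum of {self.source_id!r}: shape {vals.shape} != ({self.n},)")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"spectrum of {self.source_id!r} has negative or non-finite values")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SpectrumSet:
    """m x n matrix of PSD rows with their sequence ids."""

    spectra: np.ndarray
    ids: list[str]
    n: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.spectra, dtype=float)
        if arr.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        if arr.shape[0] < 1:
            raise ValueError("a SpectrumSet needs at least one spectrum")
        if arr.shape != (len(self.ids), self.n):
            raise ValueError(
                f"spectra shape {arr.shape} inconsistent with {len(self.ids)} ids and n={self.n}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("SpectrumSet ids must be unique")
        object.__setattr__(self, "spectra", arr)
        object.__setattr__(self, "ids", list(self.ids))

    @property
    def m(self) -> int:
        return self.spectra.shape[0]


def voss_encode(seq: DnaSequence) -> VossSignal:
    """Encode a sequence as a 4 x L binary indicator matrix (rows A, G, C, T)."""
    if len(seq.residues) == 0:
        raise ValueError(f"cannot encode empty sequence {seq.id!r}")
    chars = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    indicators = np.zeros((4, chars.size), dtype=np.uint8)
    for row, base in enumerate(CHANNELS):
        indicators[row] = chars == ord(base)
    n_ambiguous = int(chars.size - indicators.sum())
    if n_ambiguous:
        logger.info(
            "sequence %s: %d ambiguous position(s) encoded as all-zero columns",
            seq.id,
            n_ambiguous,
        )
    return VossSignal(indicators=indicators, source_id=seq.id, n_ambiguous=n_ambiguous)


def psd(signal: VossSignal, n: int | None = None, drop_dc: bool = False) -> PowerSpectrum:
    """Power spectral density of a Voss signal at common length ``n``.

    Each channel is zero-padded to ``n`` and transformed with the
    unnormalized DFT; ``values[q]`` is the sum over the four channels of
    the squared DFT magnitude at bin ``q``.  With ``drop_dc`` the DC bin
    is zeroed after the transform.

    Raises ``ValueError`` if ``n`` is smaller than the signal length
    (sequences are never truncated).
    """
    L = signal.length
    if n is None:
        n = L
    if n < L:
        raise ValueError(
            f"target spectrum length n={n} is shorter than sequence {signal.source_id!r} "
            f"(L={L}); raise n to at least {L}"
        )
    if n < 2:
        raise ValueError("spectrum length n must be at least 2")
    transform = np.fft.fft(signal.indicators.astype(float), n=n, axis=1)
    values = np.abs(transform) ** 2
    values = values.sum(axis=0)
    if drop_dc:
        values[0] = 0.0
    return PowerSpectrum(values=values, source_id=signal.source_id, n=n, orig_length=L)


def spectrum_set(
    seqs: Sequence[DnaSequence],
    n: int | str = "auto",
    drop_dc: bool = False,
) -> SpectrumSet:
    """Common-length PSD matrix for a set of sequences.

    With ``n="auto"`` the common length is the maximum sequence length.
    An explicit ``n`` shorter than the longest sequence is an error.
    """
    if not seqs:
        raise ValueError("cannot build a SpectrumSet from zero sequences")
    lengths = [len(s) for s in seqs]
    if n == "auto":
        n_common = max(lengths)
    else:
        n_common = int(n)
        too_long = [s.id for s in seqs if len(s) > n_common]
        if too_long:
            raise ValueError(
                f"{len(too_long)} sequence(s) longer than n={n_common} "
                f"(e.g. {too_long[0]!r}); sequences are never truncated"
            )
    rows = np.empty((len(seqs), n_common))
    ids = []
    for idx, seq in enumerate(seqs):
        spectrum = psd(voss_encode(seq), n=n_common, drop_dc=drop_dc)
        rows[idx] = spectrum.values
        ids.append(seq.id)
    return SpectrumSet(spectra=rows, ids=ids, n=n_common)


def spectral_distance(a: PowerSpectrum, b: PowerSpectrum) -> float:
    """Euclidean distance between two spectra of equal length."""
    if a.n != b.n:
        raise ValueError(f"spectrum lengths differ: {a.n} vs {b.n}")
    return float(np.linalg.norm(a.values - b.values))
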