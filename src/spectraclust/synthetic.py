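"""Synthetic labeled sequence families for end-to-end testing.

Each family draws one ancestor (a tiled motif or a composition-sampled
random string) and derives descendants by independent per-site
substitution with probability mu, uniform over the three alternative
bases.  No indels: family members share the ancestor's length, so padding
is only exercised by mixing families of different lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from spectraclust.sequence_io import DnaSequence, GroupTable

BASES = np.array(list("ACGT"))

#: Group level name planted labels are stored under.
FAMILY_LEVEL = "family"


@dataclass(frozen=True)
class FamilySpec:
    """Parameters for one synthetic family."""

    family_id: str
    n_sequences: int
    length: int
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str | None = None
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if self.n_sequences < 1:
            raise ValueError(f"n_sequences must be >= 1, got {self.n_sequences}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("composition must be 4 nonnegative weights summing to 1")
        if self.motif is not None:
            if not self.motif:
                raise ValueError("motif must be non-empty when given")
            if self.length < len(self.motif):
                raise ValueError(
                    f"length {self.length} is shorter than motif {self.motif!r}"
                )
            bad = set(self.motif.upper()) - set("ACGT")
            if bad:
                raise ValueError(f"motif contains non-ACGT characters: {sorted(bad)}")


def _ancestor(spec: FamilySpec, rng: np.random.Generator) -> np.ndarray:
    """Ancestor as an int array in [0, 4)."""
    if spec.motif is not None:
        motif_idx = np.array(["ACGT".index(c) for c in spec.motif.upper()])
        reps = -(-spec.length // motif_idx.size)  # ceil division
        return np.tile(motif_idx, reps)[: spec.length]
    return rng.choice(4, size=spec.length, p=np.asarray(spec.composition, dtype=float))


def generate_family(
    spec: FamilySpec, rng: np.random.Generator
) -> tuple[list[DnaSequence], str]:
    """Descendant sequences for one family plus its planted label.

    Substituted sites pick uniformly among the three other bases, so
    mu=0 reproduces the ancestor exactly.
    """
    ancestor = _ancestor(spec, rng)
    seqs: list[DnaSequence] = []
    for rep in range(spec.n_sequences):
        mutate = rng.random(spec.length) < spec.mu
        offsets = rng.integers(1, 4, size=spec.length)
        derived = np.where(mutate, (ancestor + offsets) % 4, ancestor)
        residues = "".join(BASES[derived])
        seqs.append(
            DnaSequence(id=f"{spec.family_id}-{rep + 1:03d}", residues=residues)
        )
    return seqs, spec.family_id


def generate_dataset(
    specs: Sequence[FamilySpec], seed: int
) -> tuple[list[DnaSequence], GroupTable]:
    """Concatenate families, shuffle the order, and attach planted labels.

    Deterministic for a given (specs, seed).  Family ids must be unique.
    """
    family_ids = [s.family_id for s in specs]
    if len(set(family_ids)) != len(family_ids):
        raise ValueError("duplicate family ids in dataset specs")
    rng = np.random.default_rng(seed)
    all_seqs: list[DnaSequence] = []
    labels: dict[str, list[str]] = {}
    for spec in specs:
        seqs, label = generate_family(spec, rng)
        all_seqs.extend(seqs)
        for seq in seqs:
            labels[seq.id] = [label]
    order = rng.permutation(len(all_seqs))
    shuffled = [all_seqs[i] for i in order]
    table = GroupTable.from_mapping({s.id: labels[s.id] for s in shuffled}, [FAMILY_LEVEL])
    return shuffled, table
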