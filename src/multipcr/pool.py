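"""Synthetic oligonucleotide pool design.

Every design is a fixed-length oligo built as ``adapter5 + insert + adapter3``
(defaults 20 + 108 + 21 = 149 nt), mimicking amplicon libraries in which all
templates share constant terminal priming sites.  Inserts are either fully
random (``GCall``) or constrained to exactly 50% GC (``GCfix``).  A validation
pool additionally carries copies of base designs with short motifs spliced in
at defined positions, used to measure position-dependent efficiency penalties.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

ALPHABET = "ACGT"
_BASESET = frozenset(ALPHABET)

#: Truncated-TruSeq-style terminal adapters used as defaults throughout.
#: Synthetic stand-ins with the documented lengths (20 nt / 21 nt); any real
#: library's adapters can be passed instead.
DEFAULT_ADAPTER5 = "ACACGACGCTCTTCCGATCT"
DEFAULT_ADAPTER3 = "AGACGTGTGCTCTTCCGATCT"

POSITION_KEYWORDS = ("start", "near_start", "middle", "near_end", "end")


def _check_nucleotides(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - _BASESET
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq``."""
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclasses.dataclass(frozen=True)
class AdapterPair:
    """Constant 5' and 3' adapters shared by every design in a pool."""

    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3
    name5: str = "0F"
    name3: str = "0R"

    def __post_init__(self) -> None:
        if self.adapter5:
            _check_nucleotides(self.adapter5, "adapter5")
        if self.adapter3:
            _check_nucleotides(self.adapter3, "adapter3")


@dataclasses.dataclass(frozen=True)
class MotifAnnotation:
    """Records a deliberate motif insertion into a design."""

    motif: str
    offset: int  # 0-based offset within the insert
    base_id: str  # id of the unmodified design the motif was planted into


@dataclasses.dataclass(frozen=True)
class DesignSequence:
    id: str
    insert: str
    adapters: AdapterPair
    gc_mode: str = "GCall"
    motif_annotation: Optional[MotifAnnotation] = None

    def __post_init__(self) -> None:
        _check_nucleotides(self.insert, "insert")
        if self.gc_mode not in ("GCall", "GCfix"):
            raise ValueError(f"unknown gc_mode {self.gc_mode!r}")
        if self.gc_mode == "GCfix" and gc_fraction(self.insert) != 0.5:
            raise ValueError("GCfix insert does not have exactly 50% GC")

    @property
    def full(self) -> str:
        """Full oligo sequence: adapter5 + insert + adapter3."""
        return self.adapters.adapter5 + self.insert + self.adapters.adapter3

    def __len__(self) -> int:
        return len(self.full)


@dataclasses.dataclass(frozen=True)
class MotifInsertionSpec:
    """A motif plus the position at which it replaces insert bases.

    ``position_keyword`` resolves against the insert length: ``start`` -> 0,
    ``near_start`` -> 5, ``middle`` -> floor((L-k)/2), ``near_end`` -> L-k-5,
    ``end`` -> L-k.  Alternatively an explicit ``offset`` may be given.
    """

    motif: str
    position_keyword: Optional[str] = None
    offset: Optional[int] = None

    def __post_init__(self) -> None:
        _check_nucleotides(self.motif, "motif")
        if (self.position_keyword is None) == (self.offset is None):
            raise ValueError("give exactly one of position_keyword or offset")
        if self.position_keyword is not None and self.position_keyword not in POSITION_KEYWORDS:
            raise ValueError(f"unknown position keyword {self.position_keyword!r}")

    def resolve(self, insert_length: int) -> int:
        k = len(self.motif)
        if k > insert_length:
            raise ValueError("motif longer than insert")
        if self.offset is not None:
            off = self.offset
        else:
            off = {
                "start": 0,
                "near_start": 5,
                "middle": (insert_length - k) // 2,
                "near_end": insert_length - k - 5,
                "end": insert_length - k,
            }[self.position_keyword]
        if off < 0 or off + k > insert_length:
            raise ValueError(
                f"motif of length {k} at offset {off} does not fit insert of "
                f"length {insert_length}"
            )
        return off


@dataclasses.dataclass
class OligoPool:
    designs: list[DesignSequence]
    seed: Optional[int] = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [d.id for d in self.designs]
        if len(set(ids)) != len(ids):
            raise ValueError("design ids are not unique")

    def __len__(self) -> int:
        return len(self.designs)

    def __iter__(self):
        return iter(self.designs)

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.designs]

    @property
    def inserts(self) -> list[str]:
        return [d.insert for d in self.designs]


def generate_random_insert(
    length: int, gc_mode: str = "GCall", rng: np.random.Generator | int | None = None
) -> str:
    """Generate one random insert.

    ``GCall`` draws bases i.i.d. uniformly.  ``GCfix`` draws uniformly from the
    set of sequences with exactly ``length/2`` G/C bases: half the positions
    are assigned strong (G/C) and half weak (A/T) by a random permutation, then
    each position gets one of its two bases uniformly.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(rng)
    if gc_mode == "GCall":
        idx = rng.integers(0, 4, size=length)
        return "".join(ALPHABET[i] for i in idx)
    if gc_mode == "GCfix":
        if length % 2:
            raise ValueError("GCfix requires an even insert length for exact 50% GC")
        strong = np.zeros(length, dtype=bool)
        strong[rng.permutation(length)[: length // 2]] = True
        coin = rng.integers(0, 2, size=length)
        bases = np.where(strong, np.where(coin == 0, "G", "C"), np.where(coin == 0, "A", "T"))
        return "".join(bases)
    raise ValueError(f"unknown gc_mode {gc_mode!r}")


def assemble_design(
    id: str, insert: str, adapters: AdapterPair, gc_mode: str = "GCall"
) -> DesignSequence:
    """Build a full design from an insert and an adapter pair."""
    return DesignSequence(id=id, insert=insert, adapters=adapters, gc_mode=gc_mode)


def generate_pool(
    n: int,
    gc_mode: str = "GCall",
    adapters: AdapterPair | None = None,
    seed: int | None = None,
    insert_length: int = 108,
    id_prefix: str = "SEQ",
    max_retries: int = 100,
) -> OligoPool:
    """Generate ``n`` designs with unique random inserts.

    Collisions (astronomically unlikely at 108 nt) are resolved by redrawing up
    to ``max_retries`` times per design.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    adapters = adapters if adapters is not None else AdapterPair()
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    designs: list[DesignSequence] = []
    width = max(5, len(str(n - 1)))
    for i in range(n):
        for _ in range(max_retries):
            insert = generate_random_insert(insert_length, gc_mode, rng)
            if insert not in seen:
                break
        else:
            raise RuntimeError("could not generate a unique insert after retries")
        seen.add(insert)
        designs.append(
            assemble_design(f"{id_prefix}_{i:0{width}d}", insert, adapters, gc_mode)
        )
    return OligoPool(designs=designs, seed=seed, metadata={
        "n": n, "gc_mode": gc_mode, "insert_length": insert_length,
    })


def insert_motif(
    design: DesignSequence, spec: MotifInsertionSpec, new_id: str | None = None
) -> DesignSequence:
    """Replace insert bases with a motif at the resolved offset.

    The total length never changes; the returned design carries a
    :class:`MotifAnnotation` pointing back to the base design.
    """
    off = spec.resolve(len(design.insert))
    motif = spec.motif
    insert = design.insert[:off] + motif + design.insert[off + len(motif):]
    # GCfix base designs generally lose exact 50% GC once a motif is spliced in.
    gc_mode = design.gc_mode if gc_fraction(insert) == 0.5 or design.gc_mode == "GCall" else "GCall"
    return DesignSequence(
        id=new_id if new_id is not None else f"{design.id}|{motif}@{off}",
        insert=insert,
        adapters=design.adapters,
        gc_mode=gc_mode,
        motif_annotation=MotifAnnotation(motif=motif, offset=off, base_id=design.id),
    )


def annotate_duplicates_to_longest(designs: list[DesignSequence]) -> list[DesignSequence]:
    """Re-annotate duplicate inserts to the longest motif involved.

    A short motif insertion can incidentally recreate a longer family member
    (CGTG followed by a fortuitous T reads CGTGT); all duplicate entries are
    kept but associated with the longest motif to isolate short-motif effects.
    """
    out = list(designs)
    by_insert: dict[str, list[int]] = {}
    for i, d in enumerate(out):
        if d.motif_annotation is not None:
            by_insert.setdefault(d.insert, []).append(i)
    for idxs in by_insert.values():
        if len(idxs) < 2:
            continue
        longest = max(idxs, key=lambda i: len(out[i].motif_annotation.motif))
        ann = out[longest].motif_annotation
        for i in idxs:
            out[i] = dataclasses.replace(
                out[i],
                motif_annotation=MotifAnnotation(
                    motif=ann.motif, offset=ann.offset,
                    base_id=out[i].motif_annotation.base_id,
                ),
            )
    return out


def build_validation_pool(
    n_random: int,
    motifs: Sequence[str],
    n_base: int,
    positions: Sequence[str] = POSITION_KEYWORDS,
    seed: int | None = None,
    adapters: AdapterPair | None = None,
    insert_length: int = 108,
) -> OligoPool:
    """Random designs plus systematic motif insertions for validation.

    ``n_base`` motif-free random designs are chosen as bases; each motif is
    inserted into each base at each position, yielding
    ``n_base * len(motifs) * len(positions)`` extra designs.  When two
    insertions produce an identical full sequence (a short motif recreating a
    longer one), all copies are annotated to the longest motif involved but
    every designed entry is kept.
    """
    adapters = adapters if adapters is not None else AdapterPair()
    pool = generate_pool(
        n_random, "GCall", adapters, seed, insert_length, id_prefix="RND"
    )
    candidates = [
        d for d in pool.designs if not any(m in d.insert for m in motifs)
    ]
    if len(candidates) < n_base:
        raise ValueError(
            f"only {len(candidates)} motif-free base candidates, need {n_base}"
        )
    bases = candidates[:n_base]

    motif_designs: list[DesignSequence] = []
    for b, base in enumerate(bases):
        for motif in motifs:
            for pos in positions:
                spec = MotifInsertionSpec(motif=motif, position_keyword=pos)
                motif_designs.append(
                    insert_motif(base, spec, new_id=f"MOT_{b:04d}_{motif}_{pos}")
                )

    motif_designs = annotate_duplicates_to_longest(motif_designs)
    designs = pool.designs + motif_designs
    return OligoPool(designs=designs, seed=seed, metadata={
        "n_random": n_random, "motifs": list(motifs), "n_base": n_base,
        "positions": list(positions), "insert_length": insert_length,
    })
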