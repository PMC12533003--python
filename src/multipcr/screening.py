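"""Mechanistic and practical screening of pool designs.

Covers four endpoints: scanning inserts for short reverse-complement matches
to the adapter termini (the stems of self-priming hairpins), the classical
constraint filter (GC window, homopolymer cap, hairpin free-energy floor),
score-based filtering with a matched removal count, and sequencing-depth /
sequence-recovery analysis by multinomial downsampling.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .pool import DesignSequence, OligoPool

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Hairpin / self-priming scan


@dataclasses.dataclass(frozen=True)
class HairpinHit:
    design_id: str
    adapter_end: str  # "5p" (5'-end of the 5' adapter) or "3p" (3'-end of the 3' adapter)
    stem: str  # the insert-side motif (reverse complement of the adapter stem)
    insert_offset: int
    stem_length: int
    loop_length: int


def _maximal_matches(insert: str, target: str, min_stem: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches between insert and target: (insert_off, target_off, length)."""
    hits = []
    for i in range(len(insert)):
        for j in range(len(target)):
            if insert[i] != target[j]:
                continue
            # Maximal: the match must not extend to the left.
            if i > 0 and j > 0 and insert[i - 1] == target[j - 1]:
                continue
            length = 0
            while i + length < len(insert) and j + length < len(target) and \
                    insert[i + length] == target[j + length]:
                length += 1
            if length >= min_stem:
                hits.append((i, j, length))
    return hits


def adapter_complement_scan(
    design: DesignSequence, min_stem: int = 4, terminus_window: int = 8
) -> list[HairpinHit]:
    """Find insert motifs able to fold back onto an adapter terminus.

    The 5'-most ``terminus_window`` nt of the 5' adapter and the 3'-most
    ``terminus_window`` nt of the 3' adapter are scanned for exact
    reverse-complement matches of length >= ``min_stem`` against the insert.
    The loop length is the number of bases separating the two halves of the
    stem in the folded molecule, so moving a motif away from its adapter
    enlarges the loop (and destabilises the hairpin).
    """
    hits: list[HairpinHit] = []
    insert = design.insert
    a5 = design.adapters.adapter5
    a3 = design.adapters.adapter3

    if a5:
        window = a5[:terminus_window]
        # Insert substring pairs with the adapter prefix when it equals the
        # reverse complement of part of that prefix.
        rc = reverse_complement(window)
        for i, j, length in _maximal_matches(insert, rc, min_stem):
            # j indexes into rc; the matched adapter bases are the window's
            # positions [W - j - length, W - j) with W = len(window).
            adapter_match_end = len(window) - j
            loop = (len(a5) - adapter_match_end) + i
            hits.append(HairpinHit(
                design_id=design.id, adapter_end="5p",
                stem=insert[i : i + length], insert_offset=i,
                stem_length=length, loop_length=loop,
            ))
    if a3:
        window = a3[-terminus_window:]
        rc = reverse_complement(window)
        for i, j, length in _maximal_matches(insert, rc, min_stem):
            # j indexes into rc; matched adapter bases end (len(window)-j) from
            # the adapter 3' terminus.
            offset_from_3p_end = j
            loop = (len(insert) - (i + length)) + (len(a3) - terminus_window) + \
                (terminus_window - length - offset_from_3p_end)
            hits.append(HairpinHit(
                design_id=design.id, adapter_end="3p",
                stem=insert[i : i + length], insert_offset=i,
                stem_length=length, loop_length=loop,
            ))
    return hits


# ---------------------------------------------------------------------------
# Constraint ("state of the art") filter


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def simple_hairpin_dg(seq: str, min_stem: int = 4, min_loop: int = 3) -> float:
    """Crude nearest-neighbour-flavoured hairpin free energy (kcal/mol).

    Finds the most stable intramolecular stem (exact reverse-complement match
    within the sequence separated by a loop of >= ``min_loop`` nt) and scores
    it as -1.0 kcal/mol per A:T pair and -2.0 per G:C pair, plus a logarithmic
    loop-initiation penalty.  Returns 0.0 when no hairpin can form.  This is a
    screening heuristic, not a thermodynamic model; a full secondary-structure
    backend can be plugged in via :class:`FilterCriteria`.
    """
    n = len(seq)
    best = 0.0
    rc = reverse_complement(seq)
    # Stem of length m pairing seq[i:i+m] with seq[k:k+m] (reverse complement),
    # loop = k - (i + m).
    for i in range(n - 2 * min_stem - min_loop + 1):
        for m in range(min_stem, min(12, n - i - min_stem - min_loop) + 1):
            stem = seq[i : i + m]
            target = reverse_complement(stem)
            start = i + m + min_loop
            k = seq.find(target, start)
            if k == -1:
                continue
            loop = k - (i + m)
            gc_pairs = stem.count("G") + stem.count("C")
            at_pairs = m - gc_pairs
            dg = -(2.0 * gc_pairs + 1.0 * at_pairs) + (3.0 + 1.75 * np.log(loop / 3.0))
            best = min(best, dg)
    return float(best)


@dataclasses.dataclass
class FilterCriteria:
    gc_range: tuple[float, float] = (0.40, 0.60)
    homopolymer_max: int = 4
    dg_min_kcal_per_mol: float = -15.0
    folding_backend: Callable[[str], float] = simple_hairpin_dg
    backend_name: str = "simple_hairpin_dg"


@dataclasses.dataclass
class FilterResult:
    kept_ids: list[str]
    removed_ids: list[str]
    flags: pd.DataFrame  # per-design criterion flags / scores

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def sota_filter(pool: OligoPool, criteria: FilterCriteria | None = None) -> FilterResult:
    """Remove designs failing any of GC window, homopolymer cap, or ΔG floor
    (criteria evaluated on the insert)."""
    crit = criteria if criteria is not None else FilterCriteria()
    rows = []
    for d in pool:
        gc = (d.insert.count("G") + d.insert.count("C")) / len(d.insert)
        hp = max_homopolymer(d.insert)
        try:
            dg = crit.folding_backend(d.insert)
            unevaluable = False
        except Exception:
            dg = np.nan
            unevaluable = True
        fail_gc = not (crit.gc_range[0] <= gc <= crit.gc_range[1])
        fail_hp = hp > crit.homopolymer_max
        fail_dg = (not unevaluable) and dg < crit.dg_min_kcal_per_mol
        rows.append({
            "id": d.id, "gc": gc, "homopolymer": hp, "dg": dg,
            "fail_gc": fail_gc, "fail_homopolymer": fail_hp, "fail_dg": fail_dg,
            "unevaluable": unevaluable,
            "removed": fail_gc or fail_hp or fail_dg,
        })
    flags = pd.DataFrame(rows).set_index("id")
    kept = flags.index[~flags["removed"]].tolist()
    removed = flags.index[flags["removed"]].tolist()
    return FilterResult(kept_ids=kept, removed_ids=removed, flags=flags)


def model_filter(pool: OligoPool, scores: dict[str, float] | pd.Series, n_remove: int) -> FilterResult:
    """Remove the ``n_remove`` designs with the highest low-efficiency score
    (ties broken by (score, id) for determinism)."""
    if n_remove > len(pool):
        raise ValueError("cannot remove more designs than the pool contains")
    scores = pd.Series(scores)
    missing = [d.id for d in pool if d.id not in scores.index]
    if missing:
        raise ValueError(f"missing scores for {len(missing)} designs")
    order = sorted(pool.ids, key=lambda i: (-scores[i], i))
    removed = set(order[:n_remove])
    flags = pd.DataFrame(
        {"score": [scores[i] for i in pool.ids],
         "removed": [i in removed for i in pool.ids]},
        index=pd.Index(pool.ids, name="id"),
    )
    return FilterResult(
        kept_ids=[i for i in pool.ids if i not in removed],
        removed_ids=[i for i in pool.ids if i in removed],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Depth / recovery analysis


@dataclasses.dataclass
class DepthCurve:
    depths: np.ndarray
    mean_recovery: np.ndarray
    n_replicates: int
    target: float
    min_depth_for_target: Optional[float]  # interpolated; None if unattained


def depth_recovery_curve(
    read_counts: np.ndarray,
    depths: Sequence[int],
    n_rep: int = 30,
    target: float = 0.99,
    seed: int | None = None,
) -> DepthCurve:
    """Mean fraction of designs recovered (>= 1 read) after multinomial
    downsampling to each depth, over ``n_rep`` replicates.

    The minimum depth reaching the recovery target is linearly interpolated
    on the tested grid; ``None`` when the target is not attained.
    """
    counts = np.asarray(read_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("read counts are all zero")
    p = counts / total
    rng = np.random.default_rng(seed)
    depths = np.asarray(sorted(depths))
    mean_rec = np.empty(len(depths))
    n = len(counts)
    for k, depth in enumerate(depths):
        if depth == 0:
            mean_rec[k] = 0.0
            continue
        rec = [
            float((rng.multinomial(int(depth), p) > 0).mean()) for _ in range(n_rep)
        ]
        mean_rec[k] = float(np.mean(rec))
    min_depth = None
    for k in range(len(depths)):
        if mean_rec[k] >= target:
            if k == 0:
                min_depth = float(depths[0])
            else:
                d0, d1 = depths[k - 1], depths[k]
                r0, r1 = mean_rec[k - 1], mean_rec[k]
                min_depth = float(d0 + (target - r0) / (r1 - r0) * (d1 - d0)) if r1 > r0 else float(d1)
            break
    return DepthCurve(
        depths=depths, mean_recovery=mean_rec, n_replicates=n_rep,
        target=target, min_depth_for_target=min_depth,
    )


def low_coverage_incidence(coverage: np.ndarray, threshold: float = 0.10) -> float:
    """Fraction of designs with normalised coverage below the threshold."""
    coverage = np.asarray(coverage, dtype=float)
    return float((coverage < threshold).mean())
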