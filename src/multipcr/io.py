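"""File formats: pool FASTA, coverage/estimate TSV, MEME-minimal motifs.

All tables are plain TSV with a header; sequence coordinates are 0-based,
half-open.  FASTA records carry design metadata as ``key=value`` tokens in
the description line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clumo import MotifPWM
from .efficiency import CoverageSeries
from .pool import AdapterPair, DesignSequence, MotifAnnotation, OligoPool


# ---------------------------------------------------------------------------
# Pool FASTA


def write_pool_fasta(pool: OligoPool, path: str | Path, full: bool = True) -> None:
    """One record per design; the description carries gc_mode and any motif
    annotation as key=value tokens.  ``full`` writes the 149-mer, otherwise
    the insert only."""
    records = []
    for d in pool:
        tokens = [f"gc_mode={d.gc_mode}", f"insert_length={len(d.insert)}"]
        if d.motif_annotation is not None:
            ann = d.motif_annotation
            tokens += [f"motif={ann.motif}", f"offset={ann.offset}", f"base_id={ann.base_id}"]
        records.append(SeqRecord(
            Seq(d.full if full else d.insert), id=d.id, description=" ".join(tokens)
        ))
    SeqIO.write(records, str(path), "fasta")


def read_pool_fasta(path: str | Path, adapters: AdapterPair | None = None) -> OligoPool:
    """Read a full-sequence pool FASTA written by :func:`write_pool_fasta`."""
    adapters = adapters if adapters is not None else AdapterPair()
    n5, n3 = len(adapters.adapter5), len(adapters.adapter3)
    designs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        seq = str(rec.seq)
        insert = seq[n5 : len(seq) - n3] if n3 else seq[n5:]
        ann = None
        if "motif" in tokens:
            ann = MotifAnnotation(
                motif=tokens["motif"], offset=int(tokens["offset"]),
                base_id=tokens.get("base_id", ""),
            )
        designs.append(DesignSequence(
            id=rec.id, insert=insert, adapters=adapters,
            gc_mode=tokens.get("gc_mode", "GCall"), motif_annotation=ann,
        ))
    return OligoPool(designs=designs)


def write_pool_manifest(pool: OligoPool, path: str | Path) -> None:
    rows = []
    for d in pool:
        ann = d.motif_annotation
        rows.append({
            "id": d.id, "insert": d.insert,
            "adapter5": d.adapters.name5, "adapter3": d.adapters.name3,
            "gc_mode": d.gc_mode,
            "motif": ann.motif if ann else "",
            "offset": ann.offset if ann else -1,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coverage tables


def write_coverage_tsv(series: CoverageSeries, path: str | Path) -> None:
    """Rows = design ids, columns = cumulative cycle numbers."""
    df = pd.DataFrame(
        series.coverage,
        index=pd.Index(series.ids, name="id"),
        columns=[f"c{int(c)}" for c in series.cycles],
    )
    df.to_csv(path, sep="\t")


def read_coverage_tsv(path: str | Path) -> CoverageSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cycles = [float(c.lstrip("c")) for c in df.columns]
    return CoverageSeries(ids=list(df.index), cycles=np.asarray(cycles), coverage=df.to_numpy())


def write_counts_tsv(ids: Sequence[str], cycles: Sequence[float], counts: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        counts, index=pd.Index(ids, name="id"),
        columns=[f"c{int(c)}" for c in cycles],
    ).to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cycles = np.asarray([float(c.lstrip("c")) for c in df.columns])
    return list(df.index), cycles, df.to_numpy()


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme_motifs(pwms: Sequence[MotifPWM], path: str | Path, names: Sequence[str] | None = None) -> None:
    if names is None:
        names = [f"MOTIF_{i+1}" for i in range(len(pwms))]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, pwm in zip(names, pwms):
            nsites = max(int(round(pwm.member_weights.sum())), 1)
            fh.write(f"MOTIF {name} {pwm.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.k} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in pwm.P:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme_motifs(path: str | Path) -> list[MotifPWM]:
    pwms = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("letter-probability matrix"):
            w = int(lines[i].split("w=")[1].split()[0])
            rows = [
                [float(v) for v in lines[i + 1 + j].split()] for j in range(w)
            ]
            P = np.asarray(rows)
            pwms.append(MotifPWM(P=P, members=[], member_weights=np.zeros(0)))
            i += w + 1
        else:
            i += 1
    return pwms


# ---------------------------------------------------------------------------
# Sequence logos (matplotlib letter scaling)


def plot_logo(pwm: MotifPWM, path: str | Path, title: str | None = None) -> None:
    """Information-content sequence logo rendered with matplotlib text."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    P = np.clip(pwm.P, 1e-9, 1.0)
    info = 2.0 + (P * np.log2(P)).sum(axis=1)  # bits per position
    fig, ax = plt.subplots(figsize=(0.6 * pwm.k + 1, 2.4))
    for pos in range(pwm.k):
        heights = P[pos] * info[pos]
        y = 0.0
        for idx in np.argsort(heights):
            h = heights[idx]
            if h <= 0.01:
                continue
            base = "ACGT"[idx]
            ax.text(
                pos + 0.5, y, base, ha="center", va="bottom",
                fontsize=28, color=colors[base], fontweight="bold",
                transform=ax.transData,
                # crude vertical scaling: stretch glyph to its stack share
                rotation=0, clip_on=True,
            )
            y += h
    ax.set_xlim(0, pwm.k)
    ax.set_ylim(0, 2.0)
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(pwm.k) + 0.5, [str(i) for i in range(pwm.k)])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Estimates / misc


def write_estimates_tsv(estimates: pd.DataFrame, labels: pd.Series | None, path: str | Path) -> None:
    df = estimates.copy()
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
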