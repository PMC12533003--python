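"""Synthetic benchmark scenarios and the end-to-end pipeline runner.

A benchmark scenario plants short motifs (the CGTG family by default) near
the 5' end of a small fraction of inserts and assigns those designs an
amplification-efficiency penalty that decays as the motif moves away from
the adapter -- emulating hairpin-mediated self-priming, whose loop grows
(and whose stability falls) with motif distance from the adapter.  Running
the digital twin on such a pool yields coverage data with a known
ground-truth low-efficiency tail, standing in for real serial-amplification
sequencing data in tests and demonstrations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import efficiency, io, pool as pool_mod, screening, twin as twin_mod
from .classify import (
    HyperParams,
    auprc,
    auroc,
    build_cnn,
    build_cnn_pe,
    encode_sequences,
    sample_hparams,
)
from .clumo import run_clumo
from .config import RunConfig
from .nn.train import fit, predict_scores
from .pool import MotifInsertionSpec, OligoPool, insert_motif

logger = logging.getLogger(__name__)

CGTG_FAMILY = ("CGTG", "CGTGT", "TCGTGT")

#: Relative-efficiency deficit conveyed by each motif when sitting directly
#: at the insert 5' end; longer stems are more stable hence more inhibitory.
DEFAULT_MOTIF_PENALTIES = {"CGTG": 0.08, "CGTGT": 0.12, "TCGTGT": 0.16}


@dataclasses.dataclass
class BenchmarkScenario:
    """A motif-driven low-efficiency scenario, fully generatable offline.

    The efficiency penalty is a deterministic rule of the sequence itself:
    any insert carrying a family motif starting within ``max_offset`` nt of
    its 5' end is penalised by the motif's base deficit attenuated with
    distance from the adapter (hairpin loops grow, and stability falls, as
    the motif moves 3').  Motifs are additionally planted into a small
    fraction of designs to raise carrier prevalence; chance carriers among
    the random designs are penalised by exactly the same rule.
    """

    name: str = "cgtg_5prime"
    n_designs: int = 5000
    gc_mode: str = "GCall"
    insert_length: int = 108
    motif_penalties: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MOTIF_PENALTIES)
    )
    planted_fraction: float = 0.02
    max_offset: int = 10
    #: e-folding scale (nt) of the penalty decay with motif offset.
    penalty_decay_nt: float = 25.0
    background_sigma: float = 0.01
    label_fraction: float = 0.02
    twin: twin_mod.TwinParameters = dataclasses.field(default_factory=twin_mod.TwinParameters)

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(self.motif_penalties)


@dataclasses.dataclass
class BenchmarkBundle:
    scenario: BenchmarkScenario
    pool: OligoPool
    truth: pd.DataFrame  # eps_true, planted, motif, offset per design
    run: twin_mod.TwinRun
    series: efficiency.CoverageSeries
    estimates: pd.DataFrame
    labels: pd.Series


def motif_penalty(insert: str, scenario: BenchmarkScenario) -> tuple[float, str, int]:
    """Deficit conveyed by the strongest 5'-proximal family motif in an insert.

    Scans every family motif over offsets ``0..max_offset`` and returns the
    largest decayed deficit together with the motif and offset realising it
    (0.0, "", -1 when no motif is close enough to the adapter).
    """
    best = (0.0, "", -1)
    for motif, base in scenario.motif_penalties.items():
        start = insert.find(motif)
        while 0 <= start <= scenario.max_offset:
            deficit = base * np.exp(-start / scenario.penalty_decay_nt)
            if deficit > best[0]:
                best = (deficit, motif, start)
            start = insert.find(motif, start + 1)
    return best


def make_benchmark(scenario: BenchmarkScenario | None = None, seed: int = 0) -> BenchmarkBundle:
    """Generate pool, ground truth, twin coverage, estimates and labels.

    Labels come from the fitted efficiencies (bottom ``label_fraction`` of
    estimable sequences), exactly as for real serial-amplification data;
    designs that drop out of sequencing are excluded from estimation and are
    marked non-estimable rather than labelled.
    """
    sc = scenario if scenario is not None else BenchmarkScenario()
    rng = np.random.default_rng(seed)
    base_pool = pool_mod.generate_pool(
        sc.n_designs, sc.gc_mode, seed=int(rng.integers(2**31)),
        insert_length=sc.insert_length,
    )

    # Plant motifs into a fraction of designs to raise carrier prevalence.
    n_plant = int(round(sc.planted_fraction * sc.n_designs))
    planted_idx = rng.choice(sc.n_designs, size=n_plant, replace=False)
    designs = list(base_pool.designs)
    motifs = sc.motifs
    for i in planted_idx:
        motif = motifs[rng.integers(len(motifs))]
        offset = int(rng.integers(0, sc.max_offset + 1))
        spec = MotifInsertionSpec(motif=motif, offset=offset)
        designs[i] = insert_motif(designs[i], spec, new_id=designs[i].id)

    # Penalise every design by the same sequence-determined rule.
    eps_true = np.exp(rng.normal(0.0, sc.background_sigma, size=sc.n_designs))
    motif_col = [""] * sc.n_designs
    offset_col = np.full(sc.n_designs, -1)
    carrier = np.zeros(sc.n_designs, dtype=bool)
    for i, d in enumerate(designs):
        deficit, motif, offset = motif_penalty(d.insert, sc)
        if deficit > 0:
            eps_true[i] *= 1.0 - deficit
            motif_col[i] = motif
            offset_col[i] = offset
            carrier[i] = True
    eps_true /= eps_true.mean()
    planted = np.zeros(sc.n_designs, dtype=bool)
    planted[planted_idx] = True

    bench_pool = OligoPool(designs=designs, seed=seed, metadata={"scenario": sc.name})
    run = twin_mod.simulate_serial_protocol(
        bench_pool, sc.twin, relative_efficiency=eps_true,
        rng=int(rng.integers(2**31)),
    )
    series = efficiency.CoverageSeries(ids=run.ids, cycles=run.cycles, coverage=run.coverage)
    estimates = efficiency.fit_two_parameter_model(series)
    labels = efficiency.label_low_efficiency(estimates, fraction=sc.label_fraction)

    truth = pd.DataFrame(
        {
            "eps_true": run.relative_efficiency,
            "carrier": carrier,
            "planted": planted,
            "motif": motif_col,
            "offset": offset_col,
        },
        index=pd.Index(bench_pool.ids, name="id"),
    )
    return BenchmarkBundle(
        scenario=sc, pool=bench_pool, truth=truth, run=run, series=series,
        estimates=estimates, labels=labels,
    )


def classifier_data(bundle: BenchmarkBundle) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(insert array, labels, design indices) restricted to estimable designs.

    Sequences that could not be estimated (dropouts) are excluded from
    classifier training and evaluation, mirroring how real coverage data is
    filtered before labelling.
    """
    mask = bundle.estimates["estimable"].to_numpy()
    inserts = np.asarray(bundle.pool.inserts)[mask]
    y = bundle.labels.to_numpy()[mask]
    return inserts, y, np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path, scenario: BenchmarkScenario | None = None) -> dict:
    """Design -> simulate -> fit -> label -> train -> CluMo -> screen.

    Persists each stage's outputs under ``out_dir`` and returns the manifest
    (also written as JSON) with per-stage seeds, wall times and file hashes.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "stages": []}

    def record(stage: str, t0: float, files: list[Path], **extra) -> None:
        manifest["stages"].append({
            "stage": stage,
            "wall_seconds": round(time.time() - t0, 3),
            "files": {f.name: _sha256(f) for f in files},
            **extra,
        })

    # Stage 1-3: pool, twin, fit (via the benchmark generator).
    t0 = time.time()
    sc = scenario if scenario is not None else BenchmarkScenario(
        n_designs=config.pool.n, gc_mode=config.pool.gc_mode,
        insert_length=config.pool.insert_length, twin=config.twin,
    )
    bundle = make_benchmark(sc, seed=int(rng.integers(2**31)))
    pool_fa = out / "pool.fasta"
    io.write_pool_fasta(bundle.pool, pool_fa)
    cov_tsv = out / "coverage.tsv"
    io.write_coverage_tsv(bundle.series, cov_tsv)
    est_tsv = out / "estimates.tsv"
    io.write_estimates_tsv(bundle.estimates, bundle.labels, est_tsv)
    record("design+simulate+fit", t0, [pool_fa, cov_tsv, est_tsv], n_designs=len(bundle.pool))

    # Stage 4: train the classifier on inserts.
    t0 = time.time()
    from sklearn.model_selection import train_test_split

    inserts, y, design_idx = classifier_data(bundle)
    ids_est = np.asarray(bundle.pool.ids)[design_idx]
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=config.train.test_fraction, stratify=y,
        random_state=int(rng.integers(2**31)),
    )
    X = encode_sequences(inserts)
    seed_train = int(rng.integers(2**31))
    builders = {
        "cnn_pe": lambda hp, s: build_cnn_pe(hp, X.shape[1], d=config.train.d, seed=s),
        "cnn": lambda hp, s: build_cnn(hp, X.shape[1], d=config.train.d, seed=s, with_positional_encoding=False),
    }
    if config.train.arch not in builders:
        raise ValueError(f"unsupported pipeline arch {config.train.arch!r}")
    build = builders[config.train.arch]
    tr, va = train_test_split(
        idx_train, test_size=0.1, stratify=y[idx_train],
        random_state=int(rng.integers(2**31)),
    )
    if config.train.search_iters > 0:
        best, best_score = None, -np.inf
        for _ in range(config.train.search_iters):
            hp = sample_hparams(rng)
            model = build(hp, int(rng.integers(2**31)))
            fit(model, X[tr], y[tr], lr=hp.learning_rate, batch_size=hp.batch_size,
                epochs=config.train.epochs, weight_decay=hp.weight_decay,
                seed=int(rng.integers(2**31)), X_val=X[va], y_val=y[va])
            score = auprc(predict_scores(model, X[va]), y[va])
            if score > best_score:
                best, best_score = hp, score
        hparams = best
    else:
        hparams = HyperParams()
    model = build(hparams, seed_train)
    fit(model, X[tr], y[tr], lr=hparams.learning_rate, batch_size=hparams.batch_size,
        epochs=config.train.epochs, weight_decay=hparams.weight_decay,
        seed=int(rng.integers(2**31)), X_val=X[va], y_val=y[va])
    scores_test = predict_scores(model, X[idx_test])
    metrics = {
        "test_auroc": auroc(scores_test, y[idx_test]),
        "test_auprc": auprc(scores_test, y[idx_test]),
        "hparams": dataclasses.asdict(hparams),
    }
    pred_tsv = out / "predictions.tsv"
    pd.DataFrame({
        "id": ids_est[idx_test],
        "score": scores_test,
        "label": y[idx_test],
    }).to_csv(pred_tsv, sep="\t", index=False)
    metrics_json = out / "train_metrics.json"
    io.write_json(metrics, metrics_json)
    record("train", t0, [pred_tsv, metrics_json], **{k: v for k, v in metrics.items() if k != "hparams"})

    # Stage 5: CluMo on the trained model.
    t0 = time.time()
    low = [s for s, lab in zip(inserts, y) if lab == 1]
    normal = [s for s, lab in zip(inserts, y) if lab == 0]
    cfg = dataclasses.replace(config.clumo, seed=int(rng.integers(2**31)))
    clumo_res = run_clumo(
        model, low, normal, cfg,
        substitution_labels=y[idx_test],
        substitution_sequences=list(inserts[idx_test]),
    )
    motifs_file = out / "motifs.meme"
    io.write_meme_motifs([e.pwm for e in clumo_res.significant], motifs_file)
    enrich_json = out / "enrichment.json"
    io.write_json(
        [
            {
                "consensus": e.pwm.consensus, "chi2": e.chi2, "p_raw": e.p_raw,
                "p_bonferroni": e.p_bonferroni, "contingency": e.contingency,
            }
            for e in clumo_res.enrichments
        ],
        enrich_json,
    )
    record("clumo", t0, [motifs_file, enrich_json], n_significant=len(clumo_res.significant))

    # Stage 6: screening.
    t0 = time.time()
    sota = screening.sota_filter(bundle.pool)
    X_all = encode_sequences(bundle.pool.inserts)
    scores_all = pd.Series(predict_scores(model, X_all), index=bundle.pool.ids)
    modelf = screening.model_filter(bundle.pool, scores_all, sota.n_removed)
    final_cov = bundle.series.coverage[:, -1]
    summary = {
        "sota_removed": sota.n_removed,
        "model_removed": modelf.n_removed,
        "low_coverage_incidence": {
            "none": screening.low_coverage_incidence(final_cov),
            "sota": screening.low_coverage_incidence(
                final_cov[[i in set(sota.kept_ids) for i in bundle.pool.ids]]
            ),
            "model": screening.low_coverage_incidence(
                final_cov[[i in set(modelf.kept_ids) for i in bundle.pool.ids]]
            ),
        },
    }
    screen_json = out / "screening.json"
    io.write_json(summary, screen_json)
    record("screen", t0, [screen_json], **summary["low_coverage_incidence"])

    manifest_path = out / "manifest.json"
    io.write_json(manifest, manifest_path)
    return manifest
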