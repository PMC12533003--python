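"""CluMo: global motif discovery via attribution and clustering.

Given a trained sequence classifier and a set of low-efficiency sequences,
CluMo (1) computes per-nucleotide attribution scores against a reference
input, (2) extracts, for every sequence and window size w in [4, 12], the
window with the highest cumulative attribution, (3) embeds the candidate
k-mers by pairwise Hamming distance (t-SNE) and groups them by weighted
k-means, choosing the cluster count that maximises the multiplicity-weighted
mean silhouette, building one position weight matrix (PWM) per cluster,
(4) tests each PWM's presence (max normalised PWM-window dot product >= 0.5)
for enrichment in the low-efficiency set with a chi-squared test and
Bonferroni correction, and (5) quantifies the significant motifs' importance
by substituting their occurrences in held-out data and re-scoring the model.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import scipy.stats
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .classify import auprc, auroc, encode_sequences
from .nn import Sequential
from .nn.train import predict_scores
from .pool import ALPHABET

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Step 1: attribution


def uniform_reference(L: int) -> np.ndarray:
    """The 'average sequence' reference: 0.25 in every channel."""
    return np.full((L, 4), 0.25)


def attribute(
    model: Sequential,
    X: np.ndarray,
    reference: np.ndarray | None = None,
    steps: int = 32,
    collapse: str = "sum",
    batch_size: int = 256,
) -> np.ndarray:
    """Integrated-gradients attribution of the model logit, per nucleotide.

    Integrates input gradients along the straight path from the reference to
    each input (midpoint rule) and multiplies by ``(x - reference)``, which
    approximately satisfies completeness: attributions sum to
    ``logit(x) - logit(reference)``.  Channel attributions at each position
    are collapsed to a scalar either by summing all four channels (``sum``,
    default, preserves completeness) or by taking the observed base's channel
    (``observed``).

    Returns per-position scores, shape (N, L).
    """
    if not hasattr(model, "forward") or not hasattr(model, "backward"):
        raise TypeError("model does not expose a differentiable forward/backward path")
    if collapse not in ("sum", "observed"):
        raise ValueError("collapse must be 'sum' or 'observed'")
    N, L, C = X.shape
    ref = uniform_reference(L) if reference is None else reference
    out = np.empty((N, L))
    alphas = (np.arange(steps) + 0.5) / steps
    for start in range(0, N, batch_size):
        xb = X[start : start + batch_size]
        diff = xb - ref
        grad_sum = np.zeros_like(xb)
        for a in alphas:
            model.forward(ref + a * diff, train=False)
            grad_sum += model.backward(np.ones(len(xb)))
        attr = diff * grad_sum / steps  # (B, L, 4)
        if collapse == "sum":
            out[start : start + len(xb)] = attr.sum(axis=2)
        else:
            out[start : start + len(xb)] = np.take_along_axis(
                attr, xb.argmax(axis=2)[:, :, None], axis=2
            )[:, :, 0]
    return out


# ---------------------------------------------------------------------------
# Step 2: candidate k-mers


@dataclasses.dataclass(frozen=True)
class CandidateKmer:
    bases: str
    w: int
    position: int
    cumulative_score: float
    source_id: str


def extract_candidate_kmers(
    attributions: np.ndarray,
    sequences: Sequence[str],
    w_range: tuple[int, int] = (4, 12),
    ids: Sequence[str] | None = None,
) -> list[CandidateKmer]:
    """One candidate per (sequence, window size): the window with the highest
    cumulative attribution; the leftmost window wins ties."""
    if ids is None:
        ids = [str(i) for i in range(len(sequences))]
    out: list[CandidateKmer] = []
    for attr, seq, sid in zip(attributions, sequences, ids):
        L = len(seq)
        for w in range(w_range[0], w_range[1] + 1):
            if L < w:
                logger.info("sequence %s shorter than window %d; skipped", sid, w)
                continue
            sums = sliding_window_view(attr[:L], w).sum(axis=1)
            pos = int(sums.argmax())  # argmax returns the leftmost maximum
            out.append(
                CandidateKmer(
                    bases=seq[pos : pos + w],
                    w=w,
                    position=pos,
                    cumulative_score=float(sums[pos]),
                    source_id=sid,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Step 3: clustering into PWMs


def hamming_matrix(kmers: Sequence[str]) -> np.ndarray:
    """Pairwise Hamming distances between equal-length k-mers."""
    lengths = {len(k) for k in kmers}
    if len(lengths) > 1:
        raise ValueError("k-mers must share one length")
    arr = np.array([[ord(c) for c in k] for k in kmers])
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


@dataclasses.dataclass
class KmerClustering:
    kmers: list[str]  # unique k-mers
    weights: np.ndarray  # multiplicities
    embedding: np.ndarray  # (n, 2)
    labels: np.ndarray  # cluster assignment per unique k-mer
    n_clusters: int
    silhouette: float


def embed_and_cluster(
    kmers: Sequence[str],
    c_range: tuple[int, int] = (2, 12),
    seed: int | None = None,
) -> KmerClustering:
    """t-SNE embedding of the Hamming-distance matrix followed by weighted
    k-means; the cluster count maximises the weighted mean silhouette."""
    uniq, counts = np.unique(np.asarray(kmers), return_counts=True)
    uniq = [str(u) for u in uniq]
    weights = counts.astype(float)
    n = len(uniq)
    if n < 2:
        return KmerClustering(
            kmers=uniq, weights=weights, embedding=np.zeros((n, 2)),
            labels=np.zeros(n, dtype=int), n_clusters=1, silhouette=np.nan,
        )
    D = hamming_matrix(uniq).astype(float)
    perplexity = min(30.0, max(1.0, (n - 1) / 3))
    emb = TSNE(
        n_components=2, metric="precomputed", init="random",
        perplexity=perplexity, random_state=seed,
    ).fit_transform(D)

    c_lo, c_hi = c_range
    c_hi = min(c_hi, n - 1)  # silhouette needs 2 <= C <= n-1
    best = None
    for C in range(max(2, c_lo), c_hi + 1):
        km = KMeans(n_clusters=C, n_init=10, random_state=seed)
        labels = km.fit_predict(emb, sample_weight=weights)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(np.average(silhouette_samples(emb, labels), weights=weights))
        if best is None or sil > best[0]:
            best = (sil, C, labels)
    if best is None:  # all k-mers identical in the embedding
        return KmerClustering(
            kmers=uniq, weights=weights, embedding=emb,
            labels=np.zeros(n, dtype=int), n_clusters=1, silhouette=np.nan,
        )
    sil, C, labels = best
    return KmerClustering(
        kmers=uniq, weights=weights, embedding=emb, labels=labels,
        n_clusters=C, silhouette=sil,
    )


@dataclasses.dataclass
class MotifPWM:
    P: np.ndarray  # (k, 4) position-wise base probabilities
    members: list[str]
    member_weights: np.ndarray

    @property
    def k(self) -> int:
        return self.P.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.P.argmax(axis=1))


def build_pwm(members: Sequence[str], weights: Sequence[float] | None = None) -> MotifPWM:
    """Weighted per-position base frequencies of the cluster members."""
    if not members:
        raise ValueError("cluster is empty")
    if weights is None:
        weights = np.ones(len(members))
    weights = np.asarray(weights, dtype=float)
    k = len(members[0])
    P = np.zeros((k, 4))
    for kmer, w in zip(members, weights):
        for j, b in enumerate(kmer):
            P[j, ALPHABET.index(b)] += w
    P /= P.sum(axis=1, keepdims=True)
    return MotifPWM(P=P, members=list(members), member_weights=weights)


# ---------------------------------------------------------------------------
# Step 4: presence and enrichment


def _window_onehots(sequence: str, k: int) -> np.ndarray:
    """(L-k+1, k, 4) one-hot windows of a sequence."""
    onehot = np.zeros((len(sequence), 4))
    onehot[np.arange(len(sequence)), [ALPHABET.index(b) for b in sequence]] = 1.0
    return sliding_window_view(onehot, (k, 4), axis=(0, 1))[:, 0]


def presence_score(P: np.ndarray | MotifPWM, sequence: str) -> float:
    """Max over windows of <P, W_i>/k: 1 means a perfect consensus match."""
    P = P.P if isinstance(P, MotifPWM) else np.asarray(P)
    k = P.shape[0]
    if len(sequence) < k:
        raise ValueError("sequence shorter than the PWM width")
    wins = _window_onehots(sequence, k)
    return float((wins * P).sum(axis=(1, 2)).max() / k)


def best_window_offset(P: np.ndarray | MotifPWM, sequence: str) -> tuple[int, float]:
    """Offset of the best-matching window and its presence score."""
    P = P.P if isinstance(P, MotifPWM) else np.asarray(P)
    k = P.shape[0]
    scores = (_window_onehots(sequence, k) * P).sum(axis=(1, 2)) / k
    off = int(scores.argmax())
    return off, float(scores[off])


@dataclasses.dataclass
class EnrichmentResult:
    pwm: MotifPWM
    contingency: np.ndarray  # rows: low/normal, cols: present/absent
    chi2: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    skipped: bool = False


def enrichment_test(
    pwm: MotifPWM,
    low_sequences: Sequence[str],
    normal_sequences: Sequence[str],
    n_tests: int = 1,
    alpha: float = 0.05,
    presence_threshold: float = 0.5,
    min_expected: float = 5.0,
) -> EnrichmentResult:
    """Chi-squared independence test (no continuity correction) of motif
    presence vs low-efficiency membership, Bonferroni-corrected.

    Tables violating Cochran's validity rule (any expected cell count below
    ``min_expected``, default 5) are flagged ``skipped`` and never called
    significant: the chi-squared approximation is anti-conservative there,
    and such tables arise for rare-presence PWMs whose few matches are the
    very sequences that contributed the cluster members.  Set
    ``min_expected=0`` to disable the guard.
    """
    if not low_sequences or not normal_sequences:
        raise ValueError("both sequence sets must be non-empty")
    low_present = sum(presence_score(pwm, s) >= presence_threshold for s in low_sequences)
    norm_present = sum(presence_score(pwm, s) >= presence_threshold for s in normal_sequences)
    table = np.array([
        [low_present, len(low_sequences) - low_present],
        [norm_present, len(normal_sequences) - norm_present],
    ])
    if (table.sum(axis=0) == 0).any():
        return EnrichmentResult(
            pwm=pwm, contingency=table, chi2=0.0, p_raw=1.0, p_bonferroni=1.0,
            significant=False, skipped=True,
        )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2, p_raw, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    p_bonf = min(1.0, p_raw * n_tests)
    if expected.min() < min_expected:
        return EnrichmentResult(
            pwm=pwm, contingency=table, chi2=float(chi2), p_raw=float(p_raw),
            p_bonferroni=float(p_bonf), significant=False, skipped=True,
        )
    return EnrichmentResult(
        pwm=pwm, contingency=table, chi2=float(chi2), p_raw=float(p_raw),
        p_bonferroni=float(p_bonf), significant=bool(p_bonf < alpha),
    )


def positional_profile(
    pwm: MotifPWM | str, sequences: Sequence[str]
) -> np.ndarray:
    """Histogram of best-match offsets across a sequence set.

    For a PWM the best window per sequence is used; for a literal motif every
    exact occurrence is counted.  Length of the returned histogram is
    L - k + 1 for sequence length L.
    """
    if not sequences:
        return np.zeros(0, dtype=int)
    L = len(sequences[0])
    if isinstance(pwm, str):
        k = len(pwm)
        hist = np.zeros(L - k + 1, dtype=int)
        for s in sequences:
            start = s.find(pwm)
            while start != -1:
                hist[start] += 1
                start = s.find(pwm, start + 1)
        return hist
    k = pwm.k
    hist = np.zeros(L - k + 1, dtype=int)
    for s in sequences:
        off, _ = best_window_offset(pwm, s)
        hist[off] += 1
    return hist


# ---------------------------------------------------------------------------
# Step 5: substitution analysis


@dataclasses.dataclass
class SubstitutionTrace:
    n_substituted: list[int]
    auroc: list[float]
    auprc: list[float]


def substitute_motif(
    X: np.ndarray,
    sequences: Sequence[str],
    pwm: MotifPWM,
    mode: str = "average",
    presence_threshold: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Replace each sequence's best-matching window (when called present) in
    the encoded array.

    ``average`` mode writes the average one-hot element (0.25 per channel);
    ``random`` mode writes a random one-hot base per position.
    """
    if mode not in ("average", "random"):
        raise ValueError("mode must be 'average' or 'random'")
    X = X.copy()
    k = pwm.k
    for i, s in enumerate(sequences):
        off, score = best_window_offset(pwm, s)
        if score < presence_threshold:
            continue
        if mode == "average":
            X[i, off : off + k, :] = 0.25
        else:
            idx = rng.integers(0, 4, size=k)
            X[i, off : off + k, :] = 0.0
            X[i, np.arange(off, off + k), idx] = 1.0
    return X


def substitution_analysis(
    model: Sequential,
    sequences: Sequence[str],
    labels: np.ndarray,
    motifs: Sequence[MotifPWM],
    mode: str = "average",
    presence_threshold: float = 0.5,
    seed: int | None = None,
) -> SubstitutionTrace:
    """Cumulatively substitute motifs (most significant first) and re-score.

    Entry 0 of the trace is the unmodified test performance.  Motif windows
    are located on the original sequences (no re-scan of already substituted
    regions) while the encoded array accumulates the substitutions.
    """
    rng = np.random.default_rng(seed)
    X = encode_sequences(sequences)
    trace = SubstitutionTrace(n_substituted=[0], auroc=[], auprc=[])
    scores = predict_scores(model, X)
    trace.auroc.append(auroc(scores, labels))
    trace.auprc.append(auprc(scores, labels))
    for m, pwm in enumerate(motifs, start=1):
        X = substitute_motif(X, sequences, pwm, mode, presence_threshold, rng)
        scores = predict_scores(model, X)
        trace.n_substituted.append(m)
        trace.auroc.append(auroc(scores, labels))
        trace.auprc.append(auprc(scores, labels))
    return trace


# ---------------------------------------------------------------------------
# Orchestration


@dataclasses.dataclass
class CluMoConfig:
    w_range: tuple[int, int] = (4, 12)
    c_range: tuple[int, int] = (2, 12)
    presence_threshold: float = 0.5
    alpha: float = 0.05
    attribution_steps: int = 32
    substitution_mode: str = "average"
    seed: int | None = None


@dataclasses.dataclass
class CluMoResult:
    candidates: list[CandidateKmer]
    clusterings: dict[int, KmerClustering]
    enrichments: list[EnrichmentResult]  # all PWMs tested
    significant: list[EnrichmentResult]  # sorted ascending p
    trace: SubstitutionTrace | None


def run_clumo(
    model: Sequential,
    low_sequences: Sequence[str],
    normal_sequences: Sequence[str],
    config: CluMoConfig | None = None,
    substitution_labels: np.ndarray | None = None,
    substitution_sequences: Sequence[str] | None = None,
) -> CluMoResult:
    """Run CluMo Steps 1-5 in order.

    Candidate k-mers come from the low-efficiency set only; enrichment
    contrasts the low set against the normal set.  If substitution labels are
    provided, Step 5 is run on ``substitution_sequences`` (default: the
    concatenation of both sets, low first).
    """
    cfg = config if config is not None else CluMoConfig()
    X_low = encode_sequences(low_sequences)
    attr = attribute(model, X_low, steps=cfg.attribution_steps)
    candidates = extract_candidate_kmers(attr, low_sequences, cfg.w_range)

    clusterings: dict[int, KmerClustering] = {}
    pwms: list[MotifPWM] = []
    for w in range(cfg.w_range[0], cfg.w_range[1] + 1):
        kmers = [c.bases for c in candidates if c.w == w]
        if not kmers:
            continue
        clustering = embed_and_cluster(kmers, cfg.c_range, seed=cfg.seed)
        clusterings[w] = clustering
        for c in range(clustering.n_clusters):
            mask = clustering.labels == c
            members = [k for k, m in zip(clustering.kmers, mask) if m]
            if members:
                pwms.append(build_pwm(members, clustering.weights[mask]))

    n_tests = len(pwms)
    enrichments = [
        enrichment_test(
            pwm, low_sequences, normal_sequences, n_tests=n_tests,
            alpha=cfg.alpha, presence_threshold=cfg.presence_threshold,
        )
        for pwm in pwms
    ]
    significant = sorted(
        (e for e in enrichments if e.significant), key=lambda e: (e.p_raw, -e.chi2)
    )

    trace = None
    if substitution_labels is not None:
        seqs = (
            list(substitution_sequences)
            if substitution_sequences is not None
            else list(low_sequences) + list(normal_sequences)
        )
        trace = substitution_analysis(
            model, seqs, np.asarray(substitution_labels),
            [e.pwm for e in significant], mode=cfg.substitution_mode,
            presence_threshold=cfg.presence_threshold, seed=cfg.seed,
        )
    return CluMoResult(
        candidates=candidates, clusterings=clusterings, enrichments=enrichments,
        significant=significant, trace=trace,
    )
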