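"""Multi-evidence upstream transcription-factor inference.

Four independent evidence channels nominate TFs regulating a differential
gene set:

1. **Motif channel** — promoters (and orthologous pseudo-species promoters)
   are scanned with each TF's position weight matrix using a windowed
   cluster score (sum of non-overlapping positive log-odds hits inside the
   best window); per-species gene rankings are combined by robust rank
   aggregation (Beta order statistics), and the differential set's recovery
   in the aggregated ranking is summarised by an AUC, z-scored across the
   motif collection (pass at z >= 3).
2. **ChIP channel** — externally supplied per-TF ranked target lists,
   evaluated by the same AUC/z machinery.
3. **Text-mining channel** — TF->gene interaction edges tested for overlap
   with the differential set by a one-sided hypergeometric test,
   BH-adjusted across TFs (pass at q <= 0.1).
4. **Coexpression channel** — genes ranked by correlation with each TF,
   evaluated by AUC/z.

A TF is selected when at least two channels pass. Its regulon is the set of
differential genes inside the top fraction of its best-passing ranked list;
TF->TF edges are emitted when one selected TF recovers another as a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .paired_de import bh_adjust
from .phenonet import hypergeom_upper_tail

__all__ = [
    "MotifEnrichment",
    "ChannelOutcome",
    "Regulon",
    "score_promoter",
    "rank_genes_per_species",
    "aggregate_ranks",
    "auc_recovery",
    "motif_zscores",
    "textmining_channel",
    "coexpression_channel",
    "evaluate_evidence",
    "integrate_evidence",
    "recover_targets",
    "build_regulons",
    "tf_pathway_overlap",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)


@dataclass
class MotifEnrichment:
    motif_id: str
    auc: float
    z_score: float

    @property
    def passes(self) -> bool:
        return self.z_score >= 3.0


@dataclass
class ChannelOutcome:
    """Per-TF outcome across the four channels."""

    tf: str
    motif: MotifEnrichment | None = None
    chip: MotifEnrichment | None = None
    textmining_p: float | None = None
    textmining_q: float | None = None
    coexpression: MotifEnrichment | None = None

    def passing_channels(self, tm_q_cut: float = 0.1) -> list[str]:
        passing = []
        for name in ("motif", "chip", "coexpression"):
            enr = getattr(self, name)
            if enr is not None and enr.passes:
                passing.append(name)
        if self.textmining_q is not None and self.textmining_q <= tm_q_cut:
            passing.append("textmining")
        return passing


@dataclass
class Regulon:
    tf: str
    channels: list[str]
    targets: set[str] = field(default_factory=set)
    tf_edges: list[tuple[str, str]] = field(default_factory=list)  # (regulator, regulated)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def _logodds(pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(pwm, 1e-9) / background[None, :])


#: minimum log-odds (bits) for a PWM match to count as a motif hit; cluster
#: scores sum hits above this, the conventional way sparse strong matches are
#: separated from the diffuse background of weak ones
HIT_THRESHOLD_BITS = 6.0


def _strand_scores(encoded: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Per-start log-odds on both strands (rows: genes) -> best-of-strand.

    ``encoded`` is a genes x L int8 matrix; positions with unknown bases
    score -inf. The reverse-strand score is reported at the forward start of
    the covered window.
    """
    w = lo.shape[0]
    L = encoded.shape[1]
    P = L - w + 1
    if P <= 0:
        return np.empty((encoded.shape[0], 0))
    safe = np.where(encoded >= 0, encoded, 0)
    fwd = np.zeros((encoded.shape[0], P))
    # reverse-complement hit at forward start j == scanning with the
    # reverse-complemented matrix at j
    lo_rc = lo[::-1, :][:, [3, 2, 1, 0]]
    rev = np.zeros_like(fwd)
    for k in range(w):
        col = safe[:, k:k + P]
        fwd += lo[k, col]
        rev += lo_rc[k, col]
    invalid = np.zeros((encoded.shape[0], P), bool)
    bad = encoded < 0
    for k in range(w):
        invalid |= bad[:, k:k + P]
    fwd[invalid] = -np.inf
    rev[invalid] = -np.inf
    return np.maximum(fwd, rev)


def _cluster_score(best_row: np.ndarray, w: int, seq_len: int, window_bp: int,
                   threshold: float) -> float:
    """Greedy non-overlapping hits above threshold, max sliding-window sum."""
    hit_pos = np.flatnonzero(best_row >= threshold)
    if hit_pos.size == 0:
        return 0.0
    hit_scores = best_row[hit_pos]
    order = np.lexsort((hit_pos, -hit_scores))
    occupied = np.zeros(seq_len, bool)
    pos_list, val_list = [], []
    for i in order:
        p = int(hit_pos[i])
        if occupied[p:p + w].any():
            continue
        occupied[p:p + w] = True
        pos_list.append(p)
        val_list.append(float(hit_scores[i]))
    order2 = np.argsort(pos_list)
    pos = np.asarray(pos_list)[order2]
    vals = np.asarray(val_list)[order2]
    if seq_len <= window_bp:
        return float(vals.sum())
    best_sum, acc, left = 0.0, 0.0, 0
    for right in range(len(pos)):
        acc += vals[right]
        while pos[right] - pos[left] + w > window_bp:
            acc -= vals[left]
            left += 1
        best_sum = max(best_sum, acc)
    return float(best_sum)


def score_promoter(pwm: np.ndarray, background: np.ndarray, sequence: str,
                   window_bp: int = 500,
                   hit_threshold_bits: float = HIT_THRESHOLD_BITS) -> float:
    """Windowed motif-cluster score of a promoter.

    Both strands are scanned with the log-odds matrix; matches scoring at
    least ``hit_threshold_bits`` are made non-overlapping greedily by
    descending score (ties by position), and the promoter score is the
    maximum over sliding ``window_bp`` windows of the sum of retained hits
    inside the window. Sequences shorter than the motif score 0.
    """
    w = pwm.shape[0]
    encoded = encode_sequence(sequence)
    if encoded.size < w:
        return 0.0
    lo = _logodds(pwm, background)
    best = _strand_scores(encoded[None, :], lo)[0]
    threshold = min(hit_threshold_bits, lo.max(axis=1).sum())
    threshold = max(threshold, np.nextafter(0.0, 1.0))  # hits must score > 0
    return _cluster_score(best, w, encoded.size, window_bp, threshold)


def score_promoters(pwm: np.ndarray, background: np.ndarray,
                    sequences: dict[str, str], window_bp: int = 500,
                    hit_threshold_bits: float = HIT_THRESHOLD_BITS,
                    _encoded: np.ndarray | None = None,
                    _genes: list[str] | None = None) -> dict[str, float]:
    """Vectorised :func:`score_promoter` over a promoter set of equal length.

    Falls back to the scalar path when sequences have unequal lengths.
    ``_encoded``/``_genes`` allow callers to reuse a pre-encoded matrix.
    """
    if _encoded is None:
        genes = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) > 1:
            return {g: score_promoter(pwm, background, sequences[g], window_bp,
                                      hit_threshold_bits) for g in genes}
        enc = np.vstack([encode_sequence(sequences[g]) for g in genes])
    else:
        genes, enc = _genes, _encoded
    w = pwm.shape[0]
    if enc.shape[1] < w:
        return {g: 0.0 for g in genes}
    lo = _logodds(pwm, background)
    best = _strand_scores(enc, lo)
    threshold = min(hit_threshold_bits, lo.max(axis=1).sum())
    threshold = max(threshold, np.nextafter(0.0, 1.0))
    return {
        g: _cluster_score(best[i], w, enc.shape[1], window_bp, threshold)
        for i, g in enumerate(genes)
    }


def rank_genes_per_species(scores: dict[str, float]) -> pd.Series:
    """Ranks (1 = best) by descending score; ties get the average rank."""
    s = pd.Series(scores, dtype=float)
    return s.rank(ascending=False, method="average")


def aggregate_ranks(rankings: list[pd.Series], genes: list[str] | None = None) -> pd.Series:
    """Robust rank aggregation of per-species rankings into rho scores.

    For each gene, its normalized ranks across the L lists (missing genes get
    normalized rank 1) are sorted ascending; the k-th order statistic of
    uniform ranks follows Beta(k, L-k+1), and the rho score is L times the
    minimum Beta lower-tail probability over k (a Bonferroni correction over
    the order-statistic index), clipped to 1. Returned ascending (best first).
    """
    if not rankings:
        raise ValueError("at least one ranking is required")
    if genes is None:
        genes = sorted(set().union(*(set(r.index) for r in rankings)))
    L = len(rankings)
    n_universe = len(genes)
    norm = np.ones((len(genes), L))
    for j, r in enumerate(rankings):
        # ranks normalise against the full gene universe so that partial
        # lists do not compress their members toward the bottom
        for i, g in enumerate(genes):
            if g in r.index:
                norm[i, j] = min(r.loc[g] / n_universe, 1.0)
    norm.sort(axis=1)
    k = np.arange(1, L + 1)
    beta_p = stats.beta.cdf(norm, k[None, :], L - k[None, :] + 1)
    rho = np.clip(L * beta_p.min(axis=1), 0.0, 1.0)
    out = pd.Series(rho, index=genes)
    return out.sort_values(kind="mergesort")


def auc_recovery(ranking, gene_set: set, top_fraction: float = 0.03) -> float:
    """Recovery AUC of a gene set within the top fraction of a ranking.

    ``ranking`` is an ordered gene list (best first) or a Series whose index
    order is the ranking. With X = ceil(top_fraction * n),
    AUC = (1 / (X * |set|)) * sum_{i=1..X} |set intersect top-i| in [0, 1].
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if not gene_set:
        raise ValueError("gene_set is empty")
    ordered = list(ranking.index) if isinstance(ranking, pd.Series) else list(ranking)
    n = len(ordered)
    x = int(np.ceil(top_fraction * n))
    hits = np.cumsum([1 if g in gene_set else 0 for g in ordered[:x]])
    return float(hits.sum() / (x * len(gene_set)))


def motif_zscores(aucs: dict[str, float]) -> list[MotifEnrichment]:
    """z-score each motif's AUC against the whole collection (pass at z >= 3)."""
    if len(aucs) < 2:
        raise ValueError("need at least two motifs to form z-scores")
    vals = np.array(list(aucs.values()), float)
    mean, sd = vals.mean(), vals.std(ddof=1)
    out = []
    for motif, auc in aucs.items():
        z = 0.0 if sd == 0 else (auc - mean) / sd
        out.append(MotifEnrichment(motif_id=motif, auc=float(auc), z_score=float(z)))
    return out


def textmining_channel(tf_edges: dict[str, set[str]], degs: set[str],
                       universe: set[str]) -> dict[str, tuple[float, float]]:
    """Per-TF hypergeometric overlap of text-mined targets with the DEG set,
    BH-adjusted across TFs. Returns tf -> (p, q)."""
    if not degs <= universe:
        raise ValueError("DEG set must be contained in the universe")
    tfs = sorted(tf_edges)
    ps = []
    for tf in tfs:
        targets = tf_edges[tf] & universe
        if not targets:
            ps.append(1.0)
            continue
        k = len(targets & degs)
        ps.append(hypergeom_upper_tail(k, len(universe), len(targets), len(degs)))
    qs = bh_adjust(ps)
    return {tf: (float(p), float(q)) for tf, p, q in zip(tfs, ps, qs)}


def coexpression_channel(coexpression: pd.DataFrame, degs: set[str],
                         top_fraction: float = 0.03) -> list[MotifEnrichment]:
    """Rank genes by descending correlation with each TF; AUC recovery of the
    DEG set, z-scored across TFs."""
    aucs = {}
    for tf in coexpression.index:
        row = coexpression.loc[tf].drop(labels=[tf], errors="ignore")
        order = row.sort_values(ascending=False, kind="mergesort")
        aucs[tf] = auc_recovery(list(order.index), degs, top_fraction)
    return motif_zscores(aucs)


def rank_by_coexpression(coexpression: pd.DataFrame, tf: str) -> list[str]:
    if tf not in coexpression.index:
        raise KeyError(f"unknown TF {tf!r}")
    row = coexpression.loc[tf].drop(labels=[tf], errors="ignore")
    return list(row.sort_values(ascending=False, kind="mergesort").index)


# ---------------------------------------------------------------------------
# channel orchestration
# ---------------------------------------------------------------------------

def motif_rankings(bundle, window_bp: int = 500,
                   hit_threshold_bits: float = HIT_THRESHOLD_BITS
                   ) -> dict[str, pd.Series]:
    """Aggregate cross-species motif-cluster rankings per motif (rho order)."""
    genes = bundle.genes
    encoded = {}  # species -> pre-encoded promoter matrix (or None if ragged)
    for sp in sorted(bundle.promoters):
        seqs = bundle.promoters[sp]
        if len({len(seqs[g]) for g in genes}) == 1:
            encoded[sp] = np.vstack([encode_sequence(seqs[g]) for g in genes])
        else:
            encoded[sp] = None
    rankings = {}
    for motif_id, pwm in bundle.motifs.items():
        per_species = []
        for sp in sorted(bundle.promoters):
            scores = score_promoters(pwm, bundle.background, bundle.promoters[sp],
                                     window_bp, hit_threshold_bits,
                                     _encoded=encoded[sp],
                                     _genes=genes if encoded[sp] is not None else None)
            per_species.append(rank_genes_per_species(scores))
        rankings[motif_id] = aggregate_ranks(per_species, genes=genes)
    return rankings


def evaluate_evidence(bundle, degs: set[str] | None = None, top_fraction: float = 0.03,
                      tm_q_cut: float = 0.1, window_bp: int = 500,
                      _motif_rankings: dict[str, pd.Series] | None = None
                      ) -> dict[str, ChannelOutcome]:
    """Run all four channels on an evidence bundle against a DEG set."""
    degs = set(bundle.degs if degs is None else degs)
    universe = set(bundle.genes)
    degs &= universe

    agg = _motif_rankings if _motif_rankings is not None else motif_rankings(
        bundle, window_bp)
    motif_auc = {m: auc_recovery(list(r.index), degs, top_fraction) for m, r in agg.items()}
    motif_enr = {e.motif_id: e for e in motif_zscores(motif_auc)}

    chip_auc = {tf: auc_recovery(ranked, degs, top_fraction)
                for tf, ranked in bundle.chip_rankings.items()}
    chip_enr = {e.motif_id: e for e in motif_zscores(chip_auc)}

    tm = textmining_channel(bundle.tm_edges, degs, universe)
    coex_enr = {e.motif_id: e
                for e in coexpression_channel(bundle.coexpression, degs, top_fraction)}

    outcomes = {}
    for tf in bundle.tfs:
        outcomes[tf] = ChannelOutcome(
            tf=tf,
            motif=motif_enr.get(tf),
            chip=chip_enr.get(tf),
            textmining_p=tm.get(tf, (None, None))[0],
            textmining_q=tm.get(tf, (None, None))[1],
            coexpression=coex_enr.get(tf),
        )
    return outcomes


def integrate_evidence(outcomes: dict[str, ChannelOutcome], min_channels: int = 2,
                       tm_q_cut: float = 0.1) -> list[str]:
    """Select TFs supported by at least ``min_channels`` passing channels."""
    return sorted(
        tf for tf, o in outcomes.items()
        if len(o.passing_channels(tm_q_cut)) >= min_channels
    )


def recover_targets(tf: str, ranking, degs: set[str],
                    top_fraction: float = 0.03) -> set[str]:
    """DEGs within the top fraction of a TF's ranked target list."""
    ordered = list(ranking.index) if isinstance(ranking, pd.Series) else list(ranking)
    x = int(np.ceil(top_fraction * len(ordered)))
    return {g for g in ordered[:x] if g in degs} - {tf}


def _best_ranking(tf: str, outcome: ChannelOutcome, bundle,
                  agg_rankings: dict[str, pd.Series], tm_q_cut: float):
    """Ranked list of the TF's best-passing channel (highest z among passes;
    text-mining has no ranking and is used only if nothing else passes)."""
    passing = outcome.passing_channels(tm_q_cut)
    scored = []
    for name in passing:
        if name == "motif" and tf in agg_rankings:
            scored.append((outcome.motif.z_score, "motif", list(agg_rankings[tf].index)))
        elif name == "chip":
            scored.append((outcome.chip.z_score, "chip", list(bundle.chip_rankings[tf])))
        elif name == "coexpression":
            scored.append((outcome.coexpression.z_score, "coexpression",
                           rank_by_coexpression(bundle.coexpression, tf)))
    if scored:
        scored.sort(key=lambda t: (-t[0], t[1]))
        return scored[0][2], scored[0][1]
    return None, "textmining"


def build_regulons(outcomes: dict[str, ChannelOutcome], bundle,
                   degs: set[str] | None = None, top_fraction: float = 0.03,
                   tm_q_cut: float = 0.1,
                   agg_rankings: dict[str, pd.Series] | None = None) -> list[Regulon]:
    """Regulons of the selected TFs plus TF->TF regulatory edges."""
    degs = set(bundle.degs if degs is None else degs)
    selected = integrate_evidence(outcomes, tm_q_cut=tm_q_cut)
    if agg_rankings is None:
        agg_rankings = motif_rankings(bundle)
    regulons = []
    for tf in selected:
        ranking, channel = _best_ranking(tf, outcomes[tf], bundle, agg_rankings, tm_q_cut)
        if ranking is None:  # text-mining only: targets are the mined DEG overlap
            targets = (bundle.tm_edges.get(tf, set()) & degs) - {tf}
        else:
            targets = recover_targets(tf, ranking, degs, top_fraction)
        regulons.append(Regulon(tf=tf, channels=outcomes[tf].passing_channels(tm_q_cut),
                                targets=targets))
    # TF->TF edges: B regulates A when selected TF A sits in the top fraction
    # of B's best-passing ranked list (DEG membership not required)
    sel_set = set(selected)
    for reg in regulons:
        ranking, _ = _best_ranking(reg.tf, outcomes[reg.tf], bundle, agg_rankings, tm_q_cut)
        if ranking is None:
            top = bundle.tm_edges.get(reg.tf, set())
        else:
            x = int(np.ceil(top_fraction * len(ranking)))
            top = set(ranking[:x])
        for other in sorted(sel_set - {reg.tf}):
            if other in top:
                reg.tf_edges.append((reg.tf, other))
    return regulons


def tf_pathway_overlap(regulons: list[Regulon], subnet_genes: set[str],
                       universe: set[str]) -> float:
    """One-sided hypergeometric overlap between the union of regulon targets
    and the sub-network gene set, within the given universe."""
    if not universe:
        raise ValueError("universe is empty")
    targets = set().union(*(r.targets for r in regulons)) if regulons else set()
    targets &= universe
    subnet = set(subnet_genes) & universe
    return hypergeom_upper_tail(len(targets & subnet), len(universe),
                                len(targets), len(subnet))
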