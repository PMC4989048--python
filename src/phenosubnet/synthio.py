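"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (paired differential expression,
phenotype-guided sub-network discovery, regulon inference, cross-study
overlap) is exercised on data produced here, so each generator emulates the
statistical structure the corresponding analysis assumes and records exactly
what was planted:

* paired two-site negative-binomial count matrices for eight patients, with
  a per-patient random effect, a sample-level batch shift on a subset of
  genes, and differential genes of known log2 fold change;
* a heterogeneous protein/phenotype network with a connected disease module
  whose members are annotated to designated seed phenotypes;
* a four-channel regulatory-evidence bundle (promoter motifs across
  pseudo-species, ChIP-style ranked lists, text-mining edges, TF-gene
  coexpression) with planted transcription-factor regulons.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import as_rng, check_positive, check_proportion

__all__ = [
    "SimConfig",
    "TruthTable",
    "EvidenceBundle",
    "SyntheticStudy",
    "sample_negative_binomial",
    "simulate_paired_counts",
    "simulate_hetnet",
    "simulate_gene_sets",
    "simulate_regulon_evidence",
    "simulate_study",
    "simulate_study_degs",
]

SITES = ("PLC", "DMC")  # intact posterior lateral / damaged distal medial condyle


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the paired-count simulator.

    The defaults mirror the paired two-site design of the study being
    emulated: eight patients, each contributing one intact (PLC) and one
    damaged (DMC) cartilage sample, with roughly ten percent of genes
    differential at one log2 unit. Baseline means are log-normal
    (meanlog 4, sdlog 2, natural logs) to imitate the broad dynamic range of
    RNA-seq; dispersions are drawn uniformly from ``dispersion_range`` in the
    ``Var = mu + alpha * mu**2`` parameterisation. Because the per-patient
    random effect is simulated separately, these dispersions are *residual*
    (within-joint) dispersions conditional on the patient — the quantity the
    patient-adjusted NB model estimates — not marginal cross-patient ones.
    """

    n_patients: int = 8
    n_genes: int = 2000
    de_fraction: float = 0.10
    de_log2fc_mean: float = 1.0
    dispersion_range: tuple[float, float] = (0.01, 0.3)
    batch_gene_fraction: float = 0.20
    batch_log2_shift: float = 1.0
    #: probability that a patient's two samples land in *different* batches
    #: (PLC in batch A, DMC in batch B), partially confounding batch and site.
    #: Default 0: paired samples are normally processed together, so batch is
    #: nested within patient; raise this to stress-test factor correction.
    batch_confounding: float = 0.0
    #: sd (natural log scale) of the per-patient multiplicative random effect
    patient_sd: float = 0.2
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2 for a paired design")
        check_positive(self.n_genes, "n_genes")
        check_proportion(self.de_fraction, "de_fraction")
        check_proportion(self.batch_gene_fraction, "batch_gene_fraction")
        check_proportion(self.batch_confounding, "batch_confounding")
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise ValueError("dispersion_range must be strictly positive and ordered")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        if self.patient_sd < 0:
            raise ValueError("patient_sd must be non-negative")


@dataclass
class TruthTable:
    """Planted ground truth attached to a synthetic dataset."""

    de_log2fc: dict[str, float] = field(default_factory=dict)  # gene -> true log2FC
    batch_genes: set[str] = field(default_factory=set)
    module_genes: set[str] = field(default_factory=set)
    seed_phenotypes: list[str] = field(default_factory=list)
    regulons: dict[str, set[str]] = field(default_factory=dict)  # TF -> true targets
    degs: set[str] = field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        return set(self.de_log2fc)


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def sample_negative_binomial(mean, dispersion, rng, size=None) -> np.ndarray:
    """Draw NB counts with ``Var = mu + alpha * mu**2`` via gamma-Poisson mixing.

    ``dispersion`` is the alpha of the mean-dispersion parameterisation;
    alpha -> 0 recovers the Poisson.
    """
    rng = as_rng(rng)
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(dispersion, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("dispersion must be non-negative")
    if size is not None:
        mean = np.broadcast_to(mean, size)
        alpha = np.broadcast_to(alpha, size)
    lam = np.where(
        alpha > 0,
        rng.gamma(shape=np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), 1.0),
                  scale=np.maximum(alpha, 1e-12) * mean),
        mean,
    )
    return rng.poisson(lam)


def simulate_paired_counts(config: SimConfig,
                           de_genes: list[str] | dict[str, float] | None = None):
    """Simulate a paired two-site count matrix.

    Returns ``(counts, meta, truth)`` where ``counts`` is a gene x sample
    integer DataFrame, ``meta`` a per-sample DataFrame with columns
    ``patient``, ``site`` and ``batch`` (one PLC and one DMC sample per
    patient), and ``truth`` the planted :class:`TruthTable`.

    ``de_genes`` optionally pins which genes are differential (used when the
    count simulation must be coordinated with a planted network module or
    regulon): a list gives each listed gene a random sign, a dict maps gene
    to the sign (+1/-1) of its effect. Otherwise a random ``de_fraction`` of
    genes is chosen. Differential genes carry log2 fold change
    ``+/- de_log2fc_mean``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    base_mu = rng.lognormal(mean=4.0, sigma=2.0, size=config.n_genes)

    fixed_signs = None
    if de_genes is None:
        n_de = int(round(config.de_fraction * config.n_genes))
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    else:
        missing = [g for g in de_genes if g not in gene_index]
        if missing:
            raise ValueError(f"de_genes not in gene universe: {missing[:5]}")
        if isinstance(de_genes, dict):
            fixed_signs = np.array([np.sign(de_genes[g]) for g in de_genes], float)
        de_idx = np.array([gene_index[g] for g in de_genes], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=len(de_idx))
    if fixed_signs is not None:
        signs = np.where(fixed_signs != 0, fixed_signs, signs)
    lfc = np.zeros(config.n_genes)
    lfc[de_idx] = signs * config.de_log2fc_mean

    n_batch = int(round(config.batch_gene_fraction * config.n_genes))
    batch_idx = rng.choice(config.n_genes, size=n_batch, replace=False)
    batch_flag = np.zeros(config.n_genes, bool)
    batch_flag[batch_idx] = True

    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    sample_ids, patient_col, site_col, batch_col = [], [], [], []
    for p in patients:
        split = rng.random() < config.batch_confounding
        if split:
            pair_batches = {"PLC": "A", "DMC": "B"}
        else:
            b = "A" if rng.random() < 0.5 else "B"
            pair_batches = {"PLC": b, "DMC": b}
        for site in SITES:
            sample_ids.append(f"{p}_{site}")
            patient_col.append(p)
            site_col.append(site)
            batch_col.append(pair_batches[site])
    meta = pd.DataFrame(
        {"patient": patient_col, "site": site_col, "batch": batch_col}, index=sample_ids
    )

    patient_effect = dict(
        zip(patients, rng.lognormal(mean=0.0, sigma=config.patient_sd, size=len(patients)))
    )

    alpha = rng.uniform(*config.dispersion_range, size=config.n_genes)
    lib_targets = rng.uniform(*config.library_size_range, size=len(sample_ids))

    counts = np.zeros((config.n_genes, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        mu = base_mu * patient_effect[patient_col[j]]
        if site_col[j] == "DMC":
            mu = mu * np.exp2(lfc)
        if batch_col[j] == "B":
            mu = mu * np.where(batch_flag, 2.0 ** config.batch_log2_shift, 1.0)
        mu = mu * (lib_targets[j] / mu.sum())
        counts[:, j] = sample_negative_binomial(mu, alpha, rng)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    truth = TruthTable(
        de_log2fc={genes[i]: float(lfc[i]) for i in de_idx},
        batch_genes={genes[i] for i in np.flatnonzero(batch_flag)},
    )
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# heterogeneous network
# ---------------------------------------------------------------------------

def _connected_subgraph(graph: nx.Graph, size: int, rng: np.random.Generator) -> set:
    """Grow a connected node set of the requested size by random-walk growth."""
    nodes = [n for n in graph if graph.degree(n) > 0] or list(graph)
    while True:
        start = nodes[rng.integers(len(nodes))]
        chosen = {start}
        frontier = set(graph.neighbors(start))
        while len(chosen) < size and frontier:
            pick = sorted(frontier)[rng.integers(len(frontier))]
            chosen.add(pick)
            frontier |= set(graph.neighbors(pick))
            frontier -= chosen
        if len(chosen) == size:
            return chosen
        if size > graph.number_of_nodes():
            raise ValueError("module larger than the network")


def simulate_hetnet(
    n_proteins: int,
    n_phenotypes: int,
    module_size: int,
    seed: int,
    n_seed_phenotypes: int = 4,
    background_annotation_rate: float = 0.02,
    protein_ids: list[str] | None = None,
):
    """Simulate a heterogeneous protein/phenotype network with a planted module.

    The protein-protein layer is a preferential-attachment graph (heavy-tailed
    degrees); the phenotype layer is a shallow tree; the planted disease
    module is a connected PPI subgraph whose members are annotated to the
    designated seed phenotypes. Returns ``(net, truth)`` where ``net`` is a
    :class:`phenosubnet.phenonet.HetNet`.
    """
    from .phenonet import HetNet  # deferred to avoid an import cycle

    check_positive(n_proteins, "n_proteins")
    check_positive(n_phenotypes, "n_phenotypes")
    if module_size > n_proteins:
        raise ValueError("module_size cannot exceed n_proteins")
    check_positive(module_size, "module_size")
    rng = np.random.default_rng(seed)

    proteins = protein_ids if protein_ids is not None else _gene_ids(n_proteins)
    if len(proteins) != n_proteins:
        raise ValueError("protein_ids length must equal n_proteins")
    m = min(2, n_proteins - 1)
    ba = nx.barabasi_albert_graph(n_proteins, m, seed=int(rng.integers(2**31)))
    mapping = dict(zip(range(n_proteins), proteins))
    ppi = nx.relabel_nodes(ba, mapping)

    module = _connected_subgraph(ppi, module_size, rng) if module_size > 1 else {
        proteins[int(rng.integers(n_proteins))]
    }

    phenos = [f"PH:{i + 1:04d}" for i in range(n_phenotypes)]
    # balanced tree of depth <= 2, truncated to the requested node count
    branching = max(1, math.ceil(math.sqrt(max(n_phenotypes - 1, 1))))
    pheno_edges = []
    for i in range(1, n_phenotypes):
        parent = (i - 1) // branching
        pheno_edges.append((phenos[parent], phenos[i], 1.0))

    n_seeds = min(n_seed_phenotypes, n_phenotypes)
    seed_phenos = sorted(
        phenos[i] for i in rng.choice(n_phenotypes, size=n_seeds, replace=False)
    )

    bridges = []
    for g in sorted(module):
        k = 1 + int(rng.random() < 0.5 and n_seeds > 1)
        for ph_i in rng.choice(n_seeds, size=min(k, n_seeds), replace=False):
            bridges.append((g, seed_phenos[ph_i], 1.0))
    for g in proteins:
        if g in module:
            continue
        if rng.random() < background_annotation_rate:
            bridges.append((g, phenos[int(rng.integers(n_phenotypes))], 1.0))

    ppi_edges = [(u, v, 1.0) for u, v in ppi.edges()]
    net = HetNet.from_edges(ppi_edges, pheno_edges, bridges, phenotypes=phenos)
    truth = TruthTable(module_genes=set(module), seed_phenotypes=seed_phenos)
    return net, truth


def simulate_gene_sets(
    genes: list[str],
    module_genes: set[str],
    seed: int,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 40),
):
    """Random GO-style gene sets plus one set built around the planted module."""
    from .phenonet import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = list(genes)
    sets: dict[str, set[str]] = {}
    module = sorted(module_genes)
    extras = [g for g in universe if g not in module_genes]
    pad = [extras[i] for i in rng.choice(len(extras), size=min(5, len(extras)), replace=False)]
    sets["planted_module_process"] = set(module) | set(pad)
    for i in range(n_sets - 1):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
        sets[f"random_process_{i + 1:02d}"] = {universe[j] for j in members}
    return GeneSetCollection(sets=sets, universe=set(universe))


# ---------------------------------------------------------------------------
# regulatory evidence
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclass
class EvidenceBundle:
    """Four-channel regulatory evidence for a set of candidate TFs.

    Channels: promoter motifs scored across pseudo-species, ChIP-style ranked
    target lists, text-mining TF->gene edges, and TF-gene coexpression.
    TF identifiers are drawn from the gene universe so that TF->TF regulation
    is representable.
    """

    tfs: list[str]
    genes: list[str]
    motifs: dict[str, "np.ndarray"]            # motif id -> PWM (width x 4), motif id == TF id
    background: np.ndarray                      # background base frequencies, sums to 1
    promoters: dict[str, dict[str, str]]        # species -> gene -> sequence
    chip_rankings: dict[str, list[str]]         # TF -> genes, best first
    tm_edges: dict[str, set[str]]               # TF -> text-mined targets
    coexpression: pd.DataFrame                  # TF x gene correlations
    degs: set[str]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[b] for b in arr)


_COMP = np.array([3, 2, 1, 0], dtype=np.int8)


def simulate_regulon_evidence(
    n_tfs: int = 60,
    n_genes: int = 500,
    planted_tf_count: int = 4,
    targets_per_tf: int = 10,
    seed: int = 0,
    n_species: int = 3,
    promoter_len: int = 600,
    motif_width: int = 8,
    n_extra_degs: int = 20,
    gene_ids: list[str] | None = None,
    degs: set[str] | None = None,
):
    """Simulate a four-channel evidence bundle with planted regulons.

    The first ``planted_tf_count`` TFs receive ``targets_per_tf`` true
    targets each (disjoint across TFs, excluded from the TF genes): their
    motif consensus is inserted into the target promoters of every
    pseudo-species, their ChIP scores put targets at the top of the ranked
    list, their text-mining edges cover the targets plus noise, and their
    coexpression with targets is elevated. Unplanted TFs carry pure noise in
    every channel. Returns ``(bundle, truth)``.
    """
    if planted_tf_count > n_tfs:
        raise ValueError("planted_tf_count cannot exceed n_tfs")
    if targets_per_tf > n_genes:
        raise ValueError("targets_per_tf cannot exceed n_genes")
    if planted_tf_count * targets_per_tf > n_genes - n_tfs:
        raise ValueError("not enough non-TF genes to host disjoint planted targets")
    rng = np.random.default_rng(seed)

    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    if len(genes) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    tfs = genes[:n_tfs]
    non_tf = genes[n_tfs:]

    # planted targets: disjoint samples from the candidate pool
    if degs is not None:
        pool = [g for g in non_tf if g in degs]
        if len(pool) < planted_tf_count * targets_per_tf:
            raise ValueError("provided DEG set too small to host the planted targets")
    else:
        pool = non_tf
    order = rng.permutation(len(pool))
    regulons: dict[str, set[str]] = {}
    cursor = 0
    for t in range(planted_tf_count):
        regulons[tfs[t]] = {pool[order[i]] for i in range(cursor, cursor + targets_per_tf)}
        cursor += targets_per_tf
    all_targets = set().union(*regulons.values()) if regulons else set()

    if degs is None:
        decoys = [g for g in non_tf if g not in all_targets]
        extra = {decoys[i] for i in rng.choice(len(decoys), size=min(n_extra_degs, len(decoys)),
                                               replace=False)}
        deg_set = all_targets | extra
        if not deg_set:  # no planted signal: DEGs are a random gene subset
            deg_set = {non_tf[i] for i in rng.choice(len(non_tf),
                                                     size=min(n_extra_degs, len(non_tf)),
                                                     replace=False)}
    else:
        deg_set = set(degs)

    # motif models: informative PWM around a random consensus, one per TF
    background = np.full(4, 0.25)
    motifs: dict[str, np.ndarray] = {}
    consensus: dict[str, np.ndarray] = {}
    for tf in tfs:
        cons = _random_seq(rng, motif_width)
        pwm = np.full((motif_width, 4), 0.05)
        pwm[np.arange(motif_width), cons] = 0.85
        motifs[tf] = pwm
        consensus[tf] = cons

    # promoters: random sequence; planted consensus inserted in true-target
    # promoters of every pseudo-species, random offset and strand
    promoters: dict[str, dict[str, str]] = {}
    species_tags = [f"sp{i + 1}" for i in range(n_species)]
    for sp in species_tags:
        seqs = {}
        for g in genes:
            seqs[g] = _random_seq(rng, promoter_len)
        for tf, targets in regulons.items():
            cons = consensus[tf]
            for g in targets:
                offset = int(rng.integers(0, promoter_len - motif_width + 1))
                insert = cons if rng.random() < 0.5 else _COMP[cons][::-1]
                seqs[g][offset:offset + motif_width] = insert
        promoters[sp] = {g: _decode(s) for g, s in seqs.items()}

    # ChIP channel: per-TF scores, true targets strongly shifted
    chip_rankings: dict[str, list[str]] = {}
    for tf in tfs:
        scores = rng.normal(0.0, 1.0, size=n_genes)
        if tf in regulons:
            idx = [genes.index(g) for g in regulons[tf]]
            scores[idx] += 5.0
        order_idx = np.lexsort((np.array(genes), -scores))
        chip_rankings[tf] = [genes[i] for i in order_idx]

    # text-mining channel: planted targets plus noise; pure noise otherwise
    tm_edges: dict[str, set[str]] = {}
    for tf in tfs:
        noise_n = targets_per_tf
        noise = {genes[i] for i in rng.choice(n_genes, size=noise_n, replace=False)}
        tm_edges[tf] = (set(regulons.get(tf, set())) | noise) - {tf}

    # coexpression channel: TF x gene correlations
    coexpr = rng.normal(0.0, 0.15, size=(n_tfs, n_genes))
    for t, tf in enumerate(tfs):
        if tf in regulons:
            idx = [genes.index(g) for g in regulons[tf]]
            coexpr[t, idx] = 0.8 + rng.normal(0.0, 0.05, size=len(idx))
    coexpr = pd.DataFrame(np.clip(coexpr, -0.999, 0.999), index=tfs, columns=genes)

    bundle = EvidenceBundle(
        tfs=tfs,
        genes=genes,
        motifs=motifs,
        background=background,
        promoters=promoters,
        chip_rankings=chip_rankings,
        tm_edges=tm_edges,
        coexpression=coexpr,
        degs=deg_set,
    )
    truth = TruthTable(regulons=regulons, degs=deg_set)
    return bundle, truth


# ---------------------------------------------------------------------------
# coordinated whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    counts: pd.DataFrame
    meta: pd.DataFrame
    net: object  # phenonet.HetNet
    gene_sets: object  # phenonet.GeneSetCollection
    evidence: EvidenceBundle
    truth: TruthTable


def simulate_study(
    config: SimConfig | None = None,
    n_proteins: int = 400,
    n_phenotypes: int = 12,
    module_size: int = 7,
    n_tfs: int = 60,
    planted_tf_count: int = 4,
    targets_per_tf: int = 10,
    seed: int = 0,
) -> SyntheticStudy:
    """Simulate a coherent study: counts, network, gene sets and evidence.

    Gene identifiers are shared across layers: the network proteins are the
    first ``n_proteins`` genes of the count matrix, the planted module genes
    are forced to be upregulated, and the planted regulon targets are drawn
    from the upregulated differential genes. This gives every downstream
    stage a consistent planted truth to recover.
    """
    base = config if config is not None else SimConfig()
    config = replace(base, seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(seed + 1)

    genes = _gene_ids(config.n_genes)
    proteins = genes[:n_proteins]

    net, net_truth = simulate_hetnet(
        n_proteins, n_phenotypes, module_size, seed=seed + 2, protein_ids=proteins
    )
    module = net_truth.module_genes

    # evidence universe = the network proteins; TFs are proteins outside the
    # module, and enough protein genes are reserved as upregulated hosts for
    # the planted regulon targets
    tf_pool = [g for g in proteins if g not in module]
    tfs = tf_pool[:n_tfs]
    need = planted_tf_count * targets_per_tf
    host_pool = [g for g in tf_pool[n_tfs:]]
    n_hosts = min(max(int(1.5 * need), need), len(host_pool))
    host_idx = rng.choice(len(host_pool), size=n_hosts, replace=False)
    hosts = {host_pool[i] for i in host_idx}

    # DE genes: module and hosts forced upregulated, remainder random sign
    forced_up = sorted(module | hosts)
    n_de = max(int(round(config.de_fraction * config.n_genes)), len(forced_up))
    others = [g for g in genes if g not in module and g not in hosts]
    extra_idx = rng.choice(len(others), size=n_de - len(forced_up), replace=False)
    de_spec = {g: 1.0 for g in forced_up}
    de_spec.update({others[i]: 0.0 for i in sorted(extra_idx)})  # 0 -> random sign
    counts, meta, count_truth = simulate_paired_counts(config, de_genes=de_spec)
    up_degs = {g for g, l in count_truth.de_log2fc.items() if l > 0}

    gene_sets = simulate_gene_sets(proteins, module, seed=seed + 3)

    ev_genes = tfs + [g for g in proteins if g not in tfs]
    ev_degs = up_degs & set(ev_genes)
    evidence, ev_truth = simulate_regulon_evidence(
        n_tfs=n_tfs,
        n_genes=len(ev_genes),
        planted_tf_count=planted_tf_count,
        targets_per_tf=targets_per_tf,
        seed=seed + 4,
        gene_ids=ev_genes,
        degs=ev_degs,
    )

    truth = TruthTable(
        de_log2fc=count_truth.de_log2fc,
        batch_genes=count_truth.batch_genes,
        module_genes=module,
        seed_phenotypes=net_truth.seed_phenotypes,
        regulons=ev_truth.regulons,
        degs=ev_degs,
    )
    return SyntheticStudy(counts=counts, meta=meta, net=net, gene_sets=gene_sets,
                          evidence=evidence, truth=truth)


def simulate_study_degs(
    universe: list[str],
    n_studies: int,
    common_core: int,
    per_study_extra: int,
    seed: int,
):
    """Pseudo-study DEG sets sharing a planted common core (overlap fixtures).

    Returns a list of :class:`phenosubnet.crossstudy.StudyDEGs`.
    """
    from .crossstudy import StudyDEGs

    rng = np.random.default_rng(seed)
    if common_core + per_study_extra > len(universe):
        raise ValueError("universe too small")
    core_idx = rng.choice(len(universe), size=common_core, replace=False)
    core = [universe[i] for i in core_idx]
    core_lfc = {g: float(rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 2.0)) for g in core}
    if common_core + n_studies * per_study_extra > len(universe):
        raise ValueError("universe too small for disjoint study-specific DEGs")
    studies = []
    remaining = [g for g in universe if g not in set(core)]
    shuffled = [remaining[i] for i in rng.permutation(len(remaining))]
    for s in range(n_studies):
        # study-specific DEGs are disjoint across studies, so the planted
        # core is exactly the full intersection
        extra = shuffled[s * per_study_extra:(s + 1) * per_study_extra]
        lfc = dict(core_lfc)
        for g in extra:
            lfc[g] = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 2.0))
        up = {g for g, l in lfc.items() if l > 0}
        down = {g for g, l in lfc.items() if l < 0}
        studies.append(
            StudyDEGs(label=f"study{s + 1}", universe=set(universe), up=up, down=down,
                      log2fc={g: lfc[g] for g in up | down})
        )
    return studies
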