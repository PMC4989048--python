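"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and metadata travel as TSV, networks as edge-list TSV
(source, target, layer, weight), gene sets as GMT, motifs as minimal MEME
format, promoters as FASTA (via Biopython), DE results and DEG lists as TSV,
and regulons plus run reports as JSON. Writers emit canonical (sorted,
whitespace-normalised) output so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    def __init__(self, path, line_no, field, message):
        super().__init__(f"{path}:{line_no}: field {field!r}: {message}")


# -- counts / metadata -------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if (df < 0).any().any():
        raise ParseError(path, 0, "counts", "negative count encountered")
    return df.astype(np.int64)


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample")
    for col in ("patient", "site"):
        if col not in meta.columns:
            raise ParseError(path, 1, col, "required metadata column missing")
    return meta


# -- edge lists --------------------------------------------------------------

def write_edges_tsv(edges, path) -> None:
    """Edges as (source, target, layer, weight) rows, canonically sorted."""
    rows = sorted((str(u), str(v), str(layer), float(w)) for u, v, layer, w in edges)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tlayer\tweight\n")
        for u, v, layer, w in rows:
            fh.write(f"{u}\t{v}\t{layer}\t{w:g}\n")


def read_edges_tsv(path):
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "target", "layer", "weight"]:
            raise ParseError(path, 1, "header", f"unexpected header {header}")
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(path, line_no, "row", f"expected 4 fields, got {len(parts)}")
            u, v, layer, w = parts
            if not u or not v:
                raise ParseError(path, line_no, "source/target", "empty node identifier")
            try:
                weight = float(w)
            except ValueError:
                raise ParseError(path, line_no, "weight", f"not a number: {w!r}") from None
            edges.append((u, v, layer, weight))
    return edges


def split_edges_by_layer(edges):
    by_layer: dict[str, list] = {"ppi": [], "pheno_pheno": [], "protein_pheno": []}
    for u, v, layer, w in edges:
        by_layer.setdefault(layer, []).append((u, v, w))
    return by_layer


# -- GMT ---------------------------------------------------------------------

def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, line_no, "set", "GMT rows need name, "
                                 "description and at least one member")
            sets[parts[0]] = set(parts[2:])
    return sets


# -- MEME motifs -------------------------------------------------------------

def write_meme(motifs: dict[str, np.ndarray], background: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background))
        for name in sorted(motifs):
            pwm = motifs[name]
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.shape[0]}\n")
            for row in pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path):
    motifs: dict[str, np.ndarray] = {}
    background = np.full(4, 0.25)
    name, rows, expect = None, [], 0
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            continue
        if line.startswith("letter-probability matrix"):
            expect = int(line.split("w=")[1].split()[0])
            rows = []
            for j in range(expect):
                vals = [float(v) for v in lines[i + 1 + j].split()]
                if len(vals) != 4:
                    raise ParseError(path, i + 2 + j, "pwm", "expected 4 probabilities")
                rows.append(vals)
            motifs[name] = np.array(rows)
            i += 1 + expect
            continue
        i += 1
    return motifs, background


# -- FASTA -------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- DE results / DEG lists --------------------------------------------------

DE_COLUMNS = ["baseMean", "log2FoldChange", "stat", "pvalue", "padj"]


def write_de_tsv(de_table: pd.DataFrame, path) -> None:
    de_table[DE_COLUMNS].to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_de_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, missing[0], "missing DE result column")
    return df


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# -- evidence bundle ---------------------------------------------------------

def write_evidence_bundle(bundle, out_dir) -> None:
    """Materialise an evidence bundle as its on-disk formats: MEME motifs,
    per-species promoter FASTA, ranked-list TSV, TF->gene edge TSV,
    correlation TSV and a DEG list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_meme(bundle.motifs, bundle.background, out / "motifs.meme")
    prom = out / "promoters"
    prom.mkdir(exist_ok=True)
    for sp in sorted(bundle.promoters):
        write_fasta(bundle.promoters[sp], prom / f"{sp}.fa")
    with open(out / "chip_rankings.tsv", "w") as fh:
        fh.write("tf\trank\tgene\n")
        for tf in sorted(bundle.chip_rankings):
            for i, g in enumerate(bundle.chip_rankings[tf], start=1):
                fh.write(f"{tf}\t{i}\t{g}\n")
    with open(out / "textmining_edges.tsv", "w") as fh:
        fh.write("tf\tgene\n")
        for tf in sorted(bundle.tm_edges):
            for g in sorted(bundle.tm_edges[tf]):
                fh.write(f"{tf}\t{g}\n")
    bundle.coexpression.to_csv(out / "coexpression.tsv", sep="\t",
                               index_label="tf", float_format="%.6g")
    write_gene_list(bundle.degs, out / "degs.txt")


def read_evidence_bundle(bundle_dir):
    """Inverse of :func:`write_evidence_bundle`."""
    from .synthio import EvidenceBundle

    d = Path(bundle_dir)
    motifs, background = read_meme(d / "motifs.meme")
    promoters = {}
    for fa in sorted((d / "promoters").glob("*.fa")):
        promoters[fa.stem] = read_fasta(fa)
    chip = pd.read_csv(d / "chip_rankings.tsv", sep="\t")
    chip_rankings = {
        tf: grp.sort_values("rank")["gene"].tolist()
        for tf, grp in chip.groupby("tf")
    }
    tm = pd.read_csv(d / "textmining_edges.tsv", sep="\t")
    tm_edges = {tf: set(grp["gene"]) for tf, grp in tm.groupby("tf")}
    coexpr = pd.read_csv(d / "coexpression.tsv", sep="\t", index_col="tf")
    degs = set(read_gene_list(d / "degs.txt"))
    genes = list(coexpr.columns)
    return EvidenceBundle(
        tfs=sorted(motifs), genes=genes, motifs=motifs, background=background,
        promoters=promoters, chip_rankings=chip_rankings, tm_edges=tm_edges,
        coexpression=coexpr, degs=degs,
    )


# -- regulon / report JSON ---------------------------------------------------

def write_regulons_json(regulons, outcomes, path) -> None:
    payload = []
    for reg in regulons:
        o = outcomes[reg.tf]
        payload.append({
            "tf": reg.tf,
            "channels": reg.channels,
            "motif_z": None if o.motif is None else round(o.motif.z_score, 6),
            "chip_z": None if o.chip is None else round(o.chip.z_score, 6),
            "coexpression_z": None if o.coexpression is None else round(
                o.coexpression.z_score, 6),
            "textmining_q": None if o.textmining_q is None else round(o.textmining_q, 8),
            "targets": sorted(reg.targets),
            "tf_edges": [list(e) for e in reg.tf_edges],
        })
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())
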