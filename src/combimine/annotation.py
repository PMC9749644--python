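"""Positional SNP-to-gene annotation cascade.

Each disease-associated SNP is mapped to genes in two steps: SNPs inside a
coding interval are assigned directly to the corresponding gene(s); the
remainder are assigned to the closest gene(s) whose strand-aware window —
2 kb upstream of the gene body to 0.5 kb downstream by default — contains
the SNP.  SNPs outside every window stay unassigned.

Coordinates are 1-based closed internally; BED input is converted at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "GeneModel",
    "AnnotationParams",
    "GeneAssignment",
    "map_snp_to_genes",
    "annotate_signatures",
]


@dataclass(frozen=True)
class AnnotationParams:
    upstream_window: int = 2000
    downstream_window: int = 500
    anchor: str = "body"  # or "tss"

    def __post_init__(self) -> None:
        if self.upstream_window < 0 or self.downstream_window < 0:
            raise ValueError("annotation windows must be >= 0")
        if self.anchor not in {"body", "tss"}:
            raise ValueError("anchor must be 'body' or 'tss'")


@dataclass(frozen=True)
class GeneAssignment:
    snp_id: str
    gene_id: str
    mapping_class: str  # "coding" | "proximal"
    distance: int  # bases to the gene body; 0 for coding

    def __post_init__(self) -> None:
        if self.mapping_class == "coding" and self.distance != 0:
            raise ValueError("coding assignments have distance 0")


@dataclass
class GeneModel:
    """Gene records with optional coding intervals, 1-based closed.

    ``genes`` columns: gene_id, chrom, strand (+/-), start, end.
    ``coding`` maps gene_id -> list of (start, end) coding intervals.
    """

    genes: pd.DataFrame
    coding: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "start", "end"}
        if not required.issubset(self.genes.columns):
            raise ValueError(f"gene table needs columns {sorted(required)}")
        bad = self.genes["start"] > self.genes["end"]
        if bad.any():
            raise ValueError("malformed gene interval (start > end)")
        for gid, ivals in self.coding.items():
            for s, e in ivals:
                if s > e:
                    raise ValueError(f"malformed coding interval in {gid}")

    # -- readers -----------------------------------------------------------
    @classmethod
    def from_gff3(cls, path) -> "GeneModel":
        """Load gene + CDS features from GFF3 (1-based closed, as per spec)."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        rows, coding = [], {}
        for gene in db.features_of_type("gene"):
            gid = gene.attributes.get("ID", [gene.id])[0]
            rows.append(
                {"gene_id": gid, "chrom": gene.seqid, "strand": gene.strand,
                 "start": gene.start, "end": gene.end}
            )
            cds = [
                (c.start, c.end)
                for c in db.children(gene, featuretype="CDS", order_by="start")
            ]
            if cds:
                coding[gid] = cds
        if not rows:
            raise ValueError(f"no gene features in {path}")
        return cls(genes=pd.DataFrame(rows), coding=coding)

    @classmethod
    def from_bed12(cls, path) -> "GeneModel":
        """Load genes from BED12 (0-based half-open, converted here).

        Blocks intersected with the thick region give the coding intervals.
        """
        cols = [
            "chrom", "start", "end", "name", "score", "strand",
            "thick_start", "thick_end", "rgb", "block_count",
            "block_sizes", "block_starts",
        ]
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
        rows, coding = [], {}
        for _, r in df.iterrows():
            gid = str(r["name"])
            rows.append(
                {"gene_id": gid, "chrom": str(r["chrom"]), "strand": r["strand"],
                 "start": int(r["start"]) + 1, "end": int(r["end"])}
            )
            sizes = [int(x) for x in str(r["block_sizes"]).rstrip(",").split(",")]
            starts = [int(x) for x in str(r["block_starts"]).rstrip(",").split(",")]
            thick = (int(r["thick_start"]), int(r["thick_end"]))  # 0-based half-open
            ivals = []
            for bs, sz in zip(starts, sizes):
                b0 = int(r["start"]) + bs
                b1 = b0 + sz
                s, e = max(b0, thick[0]), min(b1, thick[1])
                if s < e:
                    ivals.append((s + 1, e))  # to 1-based closed
            if ivals:
                coding[gid] = ivals
        return cls(genes=pd.DataFrame(rows), coding=coding)

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, r in self.genes.iterrows():
                fh.write(
                    f"{r['chrom']}\tcombimine\tgene\t{r['start']}\t{r['end']}\t.\t"
                    f"{r['strand']}\t.\tID={r['gene_id']}\n"
                )
                for s, e in self.coding.get(r["gene_id"], []):
                    fh.write(
                        f"{r['chrom']}\tcombimine\tCDS\t{s}\t{e}\t.\t{r['strand']}\t0\t"
                        f"ID=cds-{r['gene_id']};Parent={r['gene_id']}\n"
                    )


def _window(start: int, end: int, strand: str, p: AnnotationParams) -> tuple[int, int]:
    if p.anchor == "tss":
        anchor = start if strand == "+" else end
        body = (anchor, anchor)
    else:
        body = (start, end)
    if strand == "+":
        return body[0] - p.upstream_window, body[1] + p.downstream_window
    return body[0] - p.downstream_window, body[1] + p.upstream_window


def map_snp_to_genes(
    snp_id: str,
    chrom: str,
    pos: int,
    model: GeneModel,
    params: AnnotationParams = AnnotationParams(),
) -> list[GeneAssignment]:
    """Annotation cascade for one SNP position (1-based).

    Coding containment wins outright; otherwise the closest gene(s) whose
    window contains the SNP are reported (all of them on a distance tie).
    """
    genes = model.genes[model.genes["chrom"].astype(str) == str(chrom)]
    if genes.empty:
        raise ValueError(f"chromosome {chrom!r} not present in the gene model")
    coding_hits = []
    for _, g in genes.iterrows():
        for s, e in model.coding.get(g["gene_id"], []):
            if s <= pos <= e:
                coding_hits.append(
                    GeneAssignment(snp_id, g["gene_id"], "coding", 0)
                )
                break
    if coding_hits:
        return sorted(coding_hits, key=lambda a: a.gene_id)
    proximal = []
    for _, g in genes.iterrows():
        lo, hi = _window(int(g["start"]), int(g["end"]), g["strand"], params)
        if lo <= pos <= hi:
            if g["start"] <= pos <= g["end"]:
                dist = 0
            else:
                dist = min(abs(pos - g["start"]), abs(pos - g["end"]))
            proximal.append((dist, g["gene_id"]))
    if not proximal:
        return []
    dmin = min(d for d, _ in proximal)
    return [
        GeneAssignment(snp_id, gid, "proximal", d)
        for d, gid in sorted(proximal)
        if d == dmin
    ]


def annotate_signatures(
    signatures,
    snp_meta: pd.DataFrame,
    model: GeneModel,
    params: AnnotationParams = AnnotationParams(),
) -> tuple[pd.DataFrame, list[str]]:
    """Per-SNP gene assignments for every SNP in the given signatures.

    Returns (assignment table, unassigned SNP ids).  ``snp_meta`` must be
    indexed by SNP id with ``chrom`` and ``pos`` columns.
    """
    snp_ids: list[str] = []
    for sig in signatures:
        for st in sig.states:
            if st.snp_id not in snp_ids:
                snp_ids.append(st.snp_id)
    rows, unassigned = [], []
    for sid in snp_ids:
        meta = snp_meta.loc[sid]
        hits = map_snp_to_genes(sid, str(meta["chrom"]), int(meta["pos"]), model, params)
        if not hits:
            unassigned.append(sid)
        for h in hits:
            rows.append(
                {"snp_id": sid, "gene_id": h.gene_id,
                 "mapping_class": h.mapping_class, "distance": h.distance}
            )
    table = pd.DataFrame(rows, columns=["snp_id", "gene_id", "mapping_class", "distance"])
    return table, unassigned
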