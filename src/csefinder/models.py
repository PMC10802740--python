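"""Domain containers: gene models, ground truth, annotation gene sets.

Coordinates are half-open 0-based internally; GTF I/O converts to the
1-based inclusive convention at the file boundary and round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class ExonRecord:
    """One exon of a gene.

    ``index_in_gene`` is 1-based and strand-aware: index 1 is the 5'-most
    exon of the gene in transcription direction.
    """

    exon_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    index_in_gene: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'


@dataclass
class GeneModelSet:
    """Genes, transcripts (ordered exon-id lists) and exons."""

    genes: dict[str, Gene]
    transcripts: dict[str, list[str]]  # transcript_id -> exon ids, transcription order
    tx_gene: dict[str, str]  # transcript_id -> gene_id
    exons: dict[str, ExonRecord]

    # ---- queries -------------------------------------------------------
    def exons_of_gene(self, gene_id: str) -> list[ExonRecord]:
        out = [e for e in self.exons.values() if e.gene_id == gene_id]
        return sorted(out, key=lambda e: e.index_in_gene)

    def transcripts_of_gene(self, gene_id: str) -> dict[str, list[str]]:
        return {t: ex for t, ex in self.transcripts.items() if self.tx_gene[t] == gene_id}

    def gene_of_exon(self, exon_id: str) -> str:
        return self.exons[exon_id].gene_id

    def exon_gene_map(self) -> dict[str, str]:
        return {e.exon_id: e.gene_id for e in self.exons.values()}

    def cassette_exons(self, gene_id: str) -> list[str]:
        """Exons present in >=1 and absent from >=1 transcript of the gene."""
        txs = self.transcripts_of_gene(gene_id)
        if len(txs) < 2:
            return []
        sets = {t: set(ex) for t, ex in txs.items()}
        out = []
        for e in self.exons_of_gene(gene_id):
            in_some = any(e.exon_id in s for s in sets.values())
            out_some = any(e.exon_id not in s for s in sets.values())
            if in_some and out_some:
                out.append(e.exon_id)
        return out

    def validate(self) -> None:
        for tx, exon_ids in self.transcripts.items():
            recs = [self.exons[e] for e in exon_ids]
            by_pos = sorted(recs, key=lambda r: r.start)
            for a, b in zip(by_pos, by_pos[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping exons within transcript {tx}")
            gene = self.genes[self.tx_gene[tx]]
            order = [r.index_in_gene for r in (recs if gene.strand == "+" else recs)]
            if sorted(order) != order and sorted(order, reverse=True) != order:
                raise ValueError(f"transcript {tx} exon order not monotone")
        covered = {e for ex in self.transcripts.values() for e in ex}
        orphans = set(self.exons) - covered
        if orphans:
            raise ValueError(f"exons not in any transcript: {sorted(orphans)[:5]}")

    # ---- GTF I/O -------------------------------------------------------
    def to_gtf(self, path: str | Path) -> None:
        lines = []
        for gid in sorted(self.genes):
            gene = self.genes[gid]
            recs = self.exons_of_gene(gid)
            g_start = min(r.start for r in recs)
            g_end = max(r.end for r in recs)
            attrs = f'gene_id "{gid}";'
            lines.append(_gtf_line(gene.chrom, "gene", g_start, g_end, gene.strand, attrs))
            for tx in sorted(self.transcripts_of_gene(gid)):
                tx_recs = [self.exons[e] for e in self.transcripts[tx]]
                t_start = min(r.start for r in tx_recs)
                t_end = max(r.end for r in tx_recs)
                tattrs = f'gene_id "{gid}"; transcript_id "{tx}";'
                lines.append(_gtf_line(gene.chrom, "transcript", t_start, t_end, gene.strand, tattrs))
                for n, rec in enumerate(tx_recs, start=1):
                    eattrs = (
                        f'gene_id "{gid}"; transcript_id "{tx}"; '
                        f'exon_id "{rec.exon_id}"; exon_number "{n}"; '
                        f'exon_index "{rec.index_in_gene}";'
                    )
                    lines.append(_gtf_line(gene.chrom, "exon", rec.start, rec.end, gene.strand, eattrs))
        Path(path).write_text("".join(lines))

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GeneModelSet":
        genes: dict[str, Gene] = {}
        transcripts: dict[str, list[str]] = {}
        tx_gene: dict[str, str] = {}
        exons: dict[str, ExonRecord] = {}
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            chrom, _, feat, start, end, _, strand, _, attr_s = line.split("\t")
            attrs = _parse_attrs(attr_s)
            gid = attrs["gene_id"]
            if feat == "gene":
                genes[gid] = Gene(gid, chrom, strand)
            elif feat == "transcript":
                tid = attrs["transcript_id"]
                transcripts.setdefault(tid, [])
                tx_gene[tid] = gid
            elif feat == "exon":
                tid = attrs["transcript_id"]
                eid = attrs["exon_id"]
                rec = ExonRecord(
                    exon_id=eid,
                    gene_id=gid,
                    chrom=chrom,
                    start=int(start) - 1,  # GTF 1-based inclusive -> half-open
                    end=int(end),
                    index_in_gene=int(attrs.get("exon_index", attrs.get("exon_number", 0))),
                )
                exons.setdefault(eid, rec)
                transcripts.setdefault(tid, []).append(eid)
                tx_gene.setdefault(tid, gid)
        return cls(genes=genes, transcripts=transcripts, tx_gene=tx_gene, exons=exons)


def _gtf_line(chrom: str, feat: str, start0: int, end0: int, strand: str, attrs: str) -> str:
    return f"{chrom}\tcsefinder\t{feat}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip('"')
    return out


@dataclass
class GroundTruth:
    """What the synthetic generator planted, for parameter-recovery tests."""

    planted_gene_level: list[str] = field(default_factory=list)
    planted_as: list[tuple[str, str]] = field(default_factory=list)  # (gene, exon)
    null_genes: list[str] = field(default_factory=list)
    confounders: dict[str, list[str]] = field(default_factory=dict)
    designated_groups: dict[str, list[str]] = field(default_factory=dict)
    normal_protein_high: list[str] = field(default_factory=list)
    effect_fold: float = 1.0
    bm_expressed_genes: list[str] = field(default_factory=list)

    @property
    def planted_genes(self) -> set[str]:
        return set(self.planted_gene_level) | {g for g, _ in self.planted_as}

    def validate(self, models: GeneModelSet) -> None:
        planted = self.planted_genes
        if planted & set(self.null_genes):
            raise ValueError("planted and null gene sets overlap")
        for gene, exon in self.planted_as:
            if exon not in models.exons or models.exons[exon].gene_id != gene:
                raise ValueError(f"planted AS exon {exon} not in gene {gene}")
            if exon not in models.cassette_exons(gene):
                raise ValueError(f"planted AS exon {exon} is not a cassette exon")
        for flag, genes in self.confounders.items():
            for g in genes:
                if g not in models.genes:
                    raise ValueError(f"confounder {flag} references unknown gene {g}")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_as"] = [list(t) for t in self.planted_as]
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["planted_as"] = [tuple(t) for t in d["planted_as"]]
        return cls(**d)


@dataclass
class AnnotationSet:
    """Gene-set annotations used by the specificity filters."""

    surfaceome: set[str] = field(default_factory=set)
    matrisome: set[str] = field(default_factory=set)
    blacklist: dict[str, set[str]] = field(default_factory=dict)
    oncofetal: set[str] = field(default_factory=set)
    transmembrane: set[str] = field(default_factory=set)

    @property
    def blacklisted(self) -> set[str]:
        out: set[str] = set()
        for genes in self.blacklist.values():
            out |= genes
        return out

    def localization(self, gene_id: str) -> str | None:
        in_s = gene_id in self.surfaceome
        in_m = gene_id in self.matrisome
        if in_s and in_m:
            return "both"
        if in_s:
            return "surfaceome"
        if in_m:
            return "matrisome"
        return None

    # ---- GMT I/O -------------------------------------------------------
    def to_gmt(self, path: str | Path) -> None:
        lines = []
        for name, genes in [("surfaceome", self.surfaceome), ("matrisome", self.matrisome),
                            ("oncofetal", self.oncofetal), ("transmembrane", self.transmembrane)]:
            lines.append("\t".join([name, "csefinder"] + sorted(genes)) + "\n")
        for cat in sorted(self.blacklist):
            lines.append("\t".join([f"blacklist:{cat}", "csefinder"] + sorted(self.blacklist[cat])) + "\n")
        Path(path).write_text("".join(lines))

    @classmethod
    def from_gmt(cls, path: str | Path) -> "AnnotationSet":
        ann = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            name, genes = parts[0], set(parts[2:])
            if name.startswith("blacklist:"):
                ann.blacklist[name.split(":", 1)[1]] = genes
            elif hasattr(ann, name):
                setattr(ann, name, genes)
        return ann
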