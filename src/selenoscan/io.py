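"""File-format input/output for the pipeline.

All internal coordinates are 0-based half-open on the forward strand; GFF3
output is 1-based closed.  The conversion lives only in the writers and the
reader below, which round-trip each other.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .homology import SecSiteCall, SelenoproteinCall
from .secis import SECISElement
from .simgen import Cohort, TruthRecord

GFF_VERSION_LINE = "##gff-version 3"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _attr_str(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(s: str) -> dict:
    out = {}
    for part in s.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


class GFFRecord(dict):
    """One parsed GFF3 feature (seqid/source/type/start/end/score/strand/
    attributes); ``start0``/``end0`` give back the internal convention."""

    @property
    def start0(self) -> int:
        return int(self["start"]) - 1

    @property
    def end0(self) -> int:
        return int(self["end"])


def write_gff3(features: list[dict], path: str | Path) -> None:
    """``features``: dicts with seqid, source, type, start0, end0, score,
    strand, attrs (dict)."""
    with open(path, "w") as fh:
        fh.write(GFF_VERSION_LINE + "\n")
        for f in features:
            fh.write("\t".join([
                f["seqid"], f.get("source", "selenoscan"), f["type"],
                str(f["start0"] + 1), str(f["end0"]),
                str(f.get("score", ".")), f.get("strand", "+"), ".",
                _attr_str(f.get("attrs", {})),
            ]) + "\n")


def read_gff3(path: str | Path) -> list[GFFRecord]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        rec = GFFRecord(
            seqid=cols[0], source=cols[1], type=cols[2], start=cols[3],
            end=cols[4], score=cols[5], strand=cols[6],
        )
        rec["attrs"] = _parse_attrs(cols[8])
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

_TRUTH_COLS = [
    "gene_id", "species", "contig", "start", "end", "strand", "family",
    "member_id", "planted_class", "sec_codon_offsets", "secis_present",
    "secis_core5_start", "cluster_id", "duplication_id", "indel_codon",
    "indel_kind", "indel_length",
]


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truth:
        d = asdict(t)
        d["sec_codon_offsets"] = ",".join(map(str, t.sec_codon_offsets))
        rows.append(d)
    pd.DataFrame(rows, columns=_TRUTH_COLS).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for _, r in df.iterrows():
        offsets = tuple(
            int(x) for x in str(r["sec_codon_offsets"]).split(",") if x
        )
        out.append(TruthRecord(
            gene_id=r["gene_id"], species=r["species"], contig=r["contig"],
            start=int(r["start"]), end=int(r["end"]), strand=r["strand"],
            family=r["family"], member_id=r["member_id"],
            planted_class=r["planted_class"], sec_codon_offsets=offsets,
            secis_present=r["secis_present"] in ("True", "true", "1"),
            secis_core5_start=int(r["secis_core5_start"]),
            cluster_id=r["cluster_id"], duplication_id=r["duplication_id"],
            indel_codon=int(r["indel_codon"]), indel_kind=r["indel_kind"],
            indel_length=int(r["indel_length"]),
        ))
    return out


def write_truth_gff3(truth: list[TruthRecord], path: str | Path) -> None:
    feats = []
    for t in truth:
        attrs = {
            "ID": t.gene_id, "family": t.family, "class": t.planted_class,
            "secis": str(t.secis_present).lower(),
        }
        if t.cluster_id:
            attrs["cluster"] = t.cluster_id
        if t.duplication_id:
            attrs["duplication"] = t.duplication_id
        feats.append(dict(
            seqid=t.contig, type="gene", start0=t.start, end0=t.end,
            strand=t.strand, attrs=attrs,
        ))
    write_gff3(feats, path)


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

_CALL_COLS = [
    "species", "contig", "strand", "start", "end", "family", "ref_id",
    "score", "overall_class", "called_class", "pseudogene", "confidence",
    "motif", "secis_count", "site_classes", "frameshifts", "peptide",
]


def _sites_str(sites: list[SecSiteCall]) -> str:
    return ";".join(
        f"{s.ref_sec_index}:{s.query_residue}:{s.site_class}:"
        f"{s.window_positive_frac:.3f}"
        for s in sites
    )


def write_calls_tsv(calls: list[SelenoproteinCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "species": c.species, "contig": c.contig, "strand": c.strand,
            "start": c.start, "end": c.end, "family": c.family,
            "ref_id": c.ref_id, "score": c.score,
            "overall_class": c.overall_class, "called_class": c.called_class,
            "pseudogene": c.pseudogene, "confidence": c.confidence,
            "motif": c.motif, "secis_count": len(c.secis),
            "site_classes": _sites_str(c.site_classes),
            "frameshifts": ";".join(
                f"{e.offset_nt}:{e.kind}:{e.length}:{e.est_supported}"
                for e in c.frameshifts
            ),
            "peptide": c.peptide,
        })
    pd.DataFrame(rows, columns=_CALL_COLS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[SelenoproteinCall]:
    from .homology import FrameshiftEvent

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    calls = []
    for _, r in df.iterrows():
        sites = []
        for part in r["site_classes"].split(";"):
            if not part:
                continue
            idx, residue, cls, frac = part.split(":")
            sites.append(SecSiteCall(int(idx), residue, cls, float(frac)))
        events = []
        for part in r["frameshifts"].split(";"):
            if not part:
                continue
            off, kind, length, sup = part.split(":")
            events.append(FrameshiftEvent(
                int(off), kind, int(length), sup == "True",
            ))
        calls.append(SelenoproteinCall(
            species=r["species"], contig=r["contig"], strand=r["strand"],
            start=int(r["start"]), end=int(r["end"]), family=r["family"],
            ref_id=r["ref_id"], score=int(r["score"]), site_classes=sites,
            overall_class=r["overall_class"],
            pseudogene=r["pseudogene"] in ("True", "true", "1"),
            secis=[None] * int(r["secis_count"]),
            confidence=r["confidence"], motif=r["motif"],
            frameshifts=events, peptide=r["peptide"],
        ))
    return calls


def write_calls_gff3(calls: list[SelenoproteinCall], path: str | Path) -> None:
    feats = []
    for c in calls:
        feats.append(dict(
            seqid=c.contig, type="gene", start0=c.start, end0=c.end,
            strand=c.strand, score=c.score,
            attrs={
                "family": c.family, "class": c.called_class,
                "pseudogene": str(c.pseudogene).lower(),
                "secis_count": len(c.secis), "motif": c.motif or ".",
                "confidence": c.confidence,
            },
        ))
    write_gff3(feats, path)


def write_secis_tsv(elements: list[SECISElement], path: str | Path) -> None:
    rows = [asdict(e) for e in elements]
    cols = [
        "contig", "strand", "core5_start", "apical_start", "apical_end",
        "core3_end", "helix2_pairs", "mismatches", "score",
        "distance_from_stop",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_secis_gff3(elements: list[SECISElement], path: str | Path) -> None:
    feats = [
        dict(
            seqid=e.contig, type="SECIS_element", start0=e.core5_start,
            end0=e.core3_end, strand=e.strand, score=e.score,
            attrs={"helix2_pairs": e.helix2_pairs, "mismatches": e.mismatches},
        )
        for e in elements
    ]
    write_gff3(feats, path)


# ---------------------------------------------------------------------------
# Cohort on disk
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write genomes, transcripts, ESTs, reference DB, truth, and manifest."""
    from .refdb import write_reference_db

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for species, contigs in cohort.contigs.items():
        write_fasta([(c.id, c.seq) for c in contigs],
                    out / f"{species}.genome.fasta")
        write_fasta(cohort.transcripts[species],
                    out / f"{species}.transcripts.fasta")
        write_fasta(cohort.ests[species], out / f"{species}.ests.fasta")
    write_reference_db(cohort.ref_db, out / "reference_db.fasta")
    write_truth_tsv(cohort.truth, out / "truth.tsv")
    write_truth_gff3(cohort.truth, out / "truth.gff3")
    manifest = {
        "seed": cohort.spec.seed,
        "spec": asdict(cohort.spec),
        "species": sorted(cohort.contigs),
        "n_truth_records": len(cohort.truth),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
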