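"""File formats: FASTA/GenBank sequences, site specs, primer sheets, reports.

Sequence I/O goes through Biopython; tabular formats are TSV via pandas.
Primer order sheets use the field's rendering convention: lowercase
nucleotides carry phosphorothioate bonds, everything else is uppercase.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .seqcore import CircularSeq, DegenerateCodon, NNK
from .design import DesignReport, FragmentPlan, MutagenicPrimer
from .assembly import AssemblyResult, DsFragment
from .clone_qc import CloneRecord, LibraryReport, QcSite

__all__ = [
    "PlasmidRecord",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "read_clones_fasta",
    "write_clones_fasta",
    "read_sites",
    "write_primer_sheet",
    "read_primer_sheet",
    "write_fragments",
    "assembly_report_json",
    "library_report_tsv",
    "library_report_json",
    "load_reference_clone_matrix",
    "load_reference_primers",
    "ProjectConfig",
]


@dataclass(frozen=True)
class PlasmidRecord:
    """A plasmid plus its annotated ORF (first CDS feature), if any."""

    seq: CircularSeq
    name: str = ""
    orf_start: int | None = None
    orf_strand: str = "+"


def read_fasta(path: str | Path, topology: str = "circular") -> PlasmidRecord:
    """First record of a FASTA file.  Topology is taken from the word
    'circular' or 'linear' in the description when present, else from the
    `topology` argument."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    desc = rec.description.lower()
    if "circular" in desc:
        topology = "circular"
    elif "linear" in desc:
        topology = "linear"
    return PlasmidRecord(CircularSeq(str(rec.seq), topology), name=rec.id)


def write_fasta(path: str | Path, seq: CircularSeq, name: str = "sequence") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} {seq.topology}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq.bases[i : i + 70] + "\n")


def read_genbank(path: str | Path) -> PlasmidRecord:
    """A GenBank plasmid; topology from the LOCUS line, ORF from the first
    CDS feature (start given in coding orientation)."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "genbank"))
    topology = rec.annotations.get("topology", "linear")
    seq = CircularSeq(str(rec.seq), topology if topology in ("circular", "linear") else "linear")
    orf_start = None
    orf_strand = "+"
    for feat in rec.features:
        if feat.type == "CDS":
            if feat.location.strand == -1:
                orf_strand = "-"
                orf_start = len(seq) - int(feat.location.end)
            else:
                orf_start = int(feat.location.start)
            break
    return PlasmidRecord(seq, name=rec.id, orf_start=orf_start, orf_strand=orf_strand)


def read_clones_fasta(path: str | Path, source: str = "sequenced") -> list[CloneRecord]:
    from Bio import SeqIO

    return [CloneRecord(rec.id, str(rec.seq), source) for rec in SeqIO.parse(str(path), "fasta")]


def write_clones_fasta(path: str | Path, clones: list[CloneRecord]) -> None:
    with open(path, "w") as fh:
        for c in clones:
            fh.write(f">{c.clone_id} {c.source}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")


def read_sites(path: str | Path) -> list[dict]:
    """Target-site spec: JSON (list of objects) or TSV with columns
    site_label, aa_index, scheme; returns normalized dicts."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        raw = pd.read_csv(path, sep="\t").to_dict("records")
    out = []
    for row in raw:
        out.append(
            {
                "site_label": str(row.get("site_label", "")) or None,
                "aa_index": int(row["aa_index"]),
                "scheme": DegenerateCodon(str(row.get("scheme", "NNK") or "NNK")),
            }
        )
    return out


def write_primer_sheet(path: str | Path, primers: list[MutagenicPrimer]) -> None:
    """TSV order sheet: name, sequence (lowercase = PTO bonds),
    pto_bond_count, tm_c, gc_percent."""
    df = pd.DataFrame(
        {
            "name": [p.name for p in primers],
            "sequence": [p.render() for p in primers],
            "pto_bond_count": [p.pto_bond_count for p in primers],
            "tm_c": [round(p.tm_c, 1) for p in primers],
            "gc_percent": [round(100 * p.gc_fraction, 1) for p in primers],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_primer_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fragments(
    fasta_path: str | Path, json_path: str | Path, fragments: list[DsFragment]
) -> None:
    """Fragment set as FASTA (top strands) with a sidecar JSON holding the
    PTO bond counts and degenerate-codon positions."""
    with open(fasta_path, "w") as fh:
        for f in fragments:
            fh.write(f">{f.fragment_id}\n{f.top_strand}\n")
    meta = {
        f.fragment_id: {
            "pto_top": f.pto_top,
            "pto_bottom": f.pto_bottom,
            "degenerate_positions": [
                {"offset": d.offset, "pattern": d.scheme.pattern, "site": d.site_label}
                for d in f.degenerate_positions
            ],
        }
        for f in fragments
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def assembly_report_json(result: AssemblyResult) -> str:
    return json.dumps(
        {
            "circular": result.is_circular,
            "order": list(result.order),
            "nick_count": result.nick_count,
            "junctions": [
                {"from": j.upstream_id, "to": j.downstream_id, "overhang": j.overhang}
                for j in result.junctions
            ],
            "unmatched": list(result.unmatched),
            "ambiguous": result.ambiguous,
        },
        indent=2,
    )


def library_report_tsv(report: LibraryReport) -> str:
    """Per-position codon table with the summary rows, as TSV text."""
    return report.to_frame().to_csv(sep="\t")


def library_report_json(report: LibraryReport) -> str:
    payload = {
        "n_clones": report.n_clones,
        "distinct_codons": report.distinct_counts,
        "percent_of_max": report.percent_of_max,
        "wildtype_counts": report.wildtype_counts,
        "offscheme_counts": report.offscheme_counts,
        "duplicate_clones": report.duplicate_clones,
        "offtarget_mutations": len(report.offtarget_mutations),
        "surveyed_bases": report.surveyed_bases,
    }
    if report.surveyed_bases:
        payload["mutation_rate_per_kb"] = report.mutation_rate_per_kb
    return json.dumps(payload, indent=2)


def load_reference_clone_matrix() -> pd.DataFrame:
    """The packaged 48-clone x 5-position codon matrix observed after
    sequencing a five-site NNK library (codons lowercase as printed).

    Each column is sorted independently, as in the published table, so a
    row is not one clone's genotype; the matrix supports per-position
    tallies only."""
    with resources.files("satmut.data").joinpath("clone_codons_48x5.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="clone")


def load_reference_primers() -> pd.DataFrame:
    """The packaged ten-oligo reference order sheet (plus the two
    sub-library oligos); lowercase marks PTO bonds."""
    with resources.files("satmut.data").joinpath("reference_primers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


_CONFIG_KEYS = {
    "template": str,
    "sites": str,
    "clones": str,
    "output_dir": str,
    "seed": int,
    "log_level": str,
    "design": dict,
    "stats": dict,
}


@dataclass(frozen=True)
class ProjectConfig:
    """Validated project configuration (paths, design block, stats block).

    Unknown keys are rejected so typos fail loudly.
    """

    template: str | None = None
    sites: str | None = None
    clones: str | None = None
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"
    design: dict | None = None
    stats: dict | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "ProjectConfig":
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(path.read_text())
        else:
            raw = json.loads(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        unknown = set(raw) - set(_CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, typ in _CONFIG_KEYS.items():
            if key in raw and raw[key] is not None and not isinstance(raw[key], typ):
                raise ValueError(f"config key {key!r} must be {typ.__name__}")
        return cls(**raw)
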