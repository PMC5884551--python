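"""File formats: FASTA catalogs and alignments, tagged newick, count
matrices with sample sheets, annotation tables, and the run configuration.

Catalog FASTA headers follow the grammar ``gene|isoform|source``; alignment
FASTA headers are species names.  Count matrices are tab-delimited with
genes in rows and a companion sample sheet (sample, condition, species).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from psgscan.errors import InvalidArgumentError, ParseError
from psgscan.expression import CountMatrix
from psgscan.orthology import CdsRecord
from psgscan.selection import CodonAlignment
from psgscan.trees import Phylogeny


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_catalog(path: str | Path) -> list[CdsRecord]:
    """Read a per-species CDS catalog; headers must be gene|isoform|source."""
    records = []
    species = Path(path).stem
    line_no = {}
    with open(path) as fh:
        n = 0
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                line_no[n] = i
                n += 1
    for k, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        parts = rec.description.split("|")
        if len(parts) != 3:
            raise ParseError(
                f"catalog header {rec.description!r} is not gene|isoform|source",
                line=line_no.get(k),
            )
        gene, isoform, source = parts
        records.append(
            CdsRecord(
                gene=gene, species=species, isoform=isoform,
                seq=str(rec.seq).upper(), source=source,
            )
        )
    return records


def write_fasta_catalog(path: str | Path, records: list[CdsRecord]) -> None:
    SeqIO.write(
        [
            SeqRecord(
                Seq(r.seq), id=f"{r.gene}|{r.isoform}|{r.source}", description=""
            )
            for r in records
        ],
        str(path),
        "fasta",
    )


def read_alignment_fasta(path: str | Path) -> CodonAlignment:
    species, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        species.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not species:
        raise ParseError(f"no sequences in {path}")
    return CodonAlignment(species=species, seqs=seqs)


def write_alignment_fasta(path: str | Path, aln: CodonAlignment) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=sp, description="") for sp, s in zip(aln.species, aln.seqs)],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# newick


def read_newick(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path).read_text())


def write_newick(path: str | Path, tree: Phylogeny) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# count matrices


def write_counts(
    counts_path: str | Path, sheet_path: str | Path, counts: CountMatrix
) -> None:
    df = pd.DataFrame(counts.counts, index=counts.genes, columns=counts.samples)
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t")
    sheet = pd.DataFrame(
        {
            "sample": counts.samples,
            "condition": counts.condition,
            "species": counts.species,
        }
    )
    sheet.to_csv(sheet_path, sep="\t", index=False)


def read_counts(counts_path: str | Path, sheet_path: str | Path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t")
    required = {"sample", "condition", "species"}
    if not required <= set(sheet.columns):
        raise ParseError(f"sample sheet needs columns {sorted(required)}")
    sheet = sheet.set_index("sample").loc[list(df.columns)]
    species = sheet["species"].unique()
    if len(species) != 1:
        raise ParseError("one count matrix must hold exactly one species")
    return CountMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        counts=df.to_numpy(),
        condition=[str(c) for c in sheet["condition"]],
        species=str(species[0]),
    )


def read_de_table(path: str | Path, q_threshold: float = 0.1) -> list:
    """Read an externally produced DE table (gene, lfc, p, q) as DeRecords.

    Lets real differential-expression output stand in for the built-in NB
    Wald stage; every downstream operation consumes the same records.
    """
    from psgscan.expression import DeRecord

    df = pd.read_csv(path, sep="\t")
    required = {"gene", "lfc", "p", "q"}
    if not required <= set(df.columns):
        raise ParseError(f"DE table needs columns {sorted(required)}")
    return [
        DeRecord(
            gene=str(r.gene), lfc=float(r.lfc), p=float(r.p), q=float(r.q),
            regulated=bool(r.q <= q_threshold),
        )
        for r in df.itertuples()
    ]


def read_annotation(path: str | Path) -> list[tuple[str, str]]:
    """Two-column tab-delimited (gene, term) pairs; '#' lines are comments."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError("annotation rows need exactly 2 columns", line=i)
            pairs.append((parts[0], parts[1]))
    return pairs


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Serialized as sorted ``key = value`` lines; round-trips losslessly.
    """

    seed: int = 1
    outdir: str = "psgscan_run"
    # synthetic inputs
    n_taxa: int = 4
    tree_depth: float = 0.05
    n_scan_genes: int = 8
    n_codons: int = 150
    selected_fraction: float = 0.25
    kappa: float = 2.0
    omega0: float = 0.2
    omega2: float = 8.0
    p0: float = 0.5
    p1: float = 0.3
    foregrounds: tuple[str, ...] = ("sp1",)
    n_expression_genes: int = 1500
    dispersion: float = 0.05
    regulated_fraction: float = 0.2
    q1_prob: float = 0.8
    n_terms: int = 20
    # thresholds
    candidate_q: float = 0.1
    de_q: float = 0.1
    site_posterior: float = 0.5
    # stages
    stages: tuple[str, ...] = ("simulate", "orthologs", "scan", "expression", "enrich", "report")
    n_starts: int = 2

    def __post_init__(self):
        for name in ("candidate_q", "de_q", "site_posterior"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidArgumentError(f"{name} must lie in (0, 1]")

    def to_text(self) -> str:
        lines = []
        for f in sorted(dataclasses.fields(self), key=lambda f: f.name):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for i, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError("expected 'key = value'", line=i)
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ParseError(f"unknown config key {key!r}", line=i)
            ftype = fields[key].type
            if ftype.startswith("tuple"):
                kwargs[key] = tuple(x for x in raw.split(",") if x)
            elif ftype == "int":
                kwargs[key] = int(raw)
            elif ftype == "float":
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())


def write_summary(path: str | Path, summary: dict) -> None:
    """Machine-readable run summary with deterministic formatting."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=default) + "\n")
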