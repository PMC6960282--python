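"""Genomes-as-gene-sets, role manifests and score tables in plain-text formats.

A genome enters the pipeline as a nucleotide multi-FASTA with one record per
gene (the output shape of gene callers such as Prodigal).  An optional
``[class=rRNA|tRNA|other]`` token in the record description marks structural
RNAs so they can be excluded before ANI/AF computation; records without the
token are protein-coding.  Cohorts are described by a tab-separated manifest
assigning each genome a role (``primary_reference`` / ``type_species`` /
``non_type``), a genus and the family/order under analysis.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import MisigError

# IUPAC nucleotide alphabet (ambiguity codes retained, scored as mismatches
# downstream).
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")

_CLASS_TOKEN = re.compile(r"\[class=([A-Za-z_]+)\]")


class FeatureClass(str, Enum):
    protein_coding = "protein_coding"
    rRNA = "rRNA"
    tRNA = "tRNA"
    other = "other"


class Role(str, Enum):
    primary_reference = "primary_reference"
    type_species = "type_species"
    non_type = "non_type"


@dataclass(frozen=True, slots=True)
class Gene:
    """A single gene: an id unique within its genome and its nucleotide sequence."""

    gene_id: str
    sequence: str
    feature_class: FeatureClass = FeatureClass.protein_coding

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise MisigError("invalid gene: empty gene_id")
        if not self.sequence:
            raise MisigError(f"invalid sequence: gene {self.gene_id!r} is empty")
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            raise MisigError(
                f"invalid sequence: gene {self.gene_id!r} contains non-IUPAC "
                f"characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class GeneSet:
    """A genome represented by its gene sequences."""

    genome_id: str
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise MisigError(f"duplicate gene id: {dup!r} in genome {self.genome_id!r}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def total_coding_length(self) -> int:
        """Summed length (nt) of the protein-coding genes."""
        return sum(
            g.length for g in self.genes if g.feature_class is FeatureClass.protein_coding
        )


@dataclass(frozen=True, slots=True)
class ManifestEntry:
    genome_id: str
    path: Path
    role: Role
    genus: str
    taxon_label: str
    is_proxy: bool = False


@dataclass(frozen=True, slots=True)
class PairwiseScore:
    """Directional and averaged ANI/AF between two genomes.

    ANI values are percentages, AF values are fractions of total protein-coding
    length.  When fewer than ``min_bbh`` orthologs are found the ANI fields are
    ``None`` and ``defined`` is False; AF is still reported (it is 0 when there
    are no BBHs at all).
    """

    genome_a: str
    genome_b: str
    ani_12: float | None
    ani_21: float | None
    af_12: float
    af_21: float
    n_bbh: int
    defined: bool

    @property
    def ani_mean(self) -> float | None:
        if self.ani_12 is None or self.ani_21 is None:
            return None
        return (self.ani_12 + self.ani_21) / 2.0

    @property
    def af_mean(self) -> float:
        return (self.af_12 + self.af_21) / 2.0

    def swapped(self) -> "PairwiseScore":
        """The same comparison seen from genome_b's side."""
        return PairwiseScore(
            genome_a=self.genome_b,
            genome_b=self.genome_a,
            ani_12=self.ani_21,
            ani_21=self.ani_12,
            af_12=self.af_21,
            af_21=self.af_12,
            n_bbh=self.n_bbh,
            defined=self.defined,
        )


# ---------------------------------------------------------------------------
# FASTA gene sets
# ---------------------------------------------------------------------------

def read_gene_set(path: str | Path, genome_id: str | None = None) -> GeneSet:
    """Read a one-record-per-gene nucleotide FASTA into a :class:`GeneSet`.

    ``feature_class`` is parsed from an optional ``[class=...]`` header token;
    records without it are protein-coding.  Sequences are uppercased.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    genes: list[Gene] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise MisigError(f"duplicate gene id: {rec.id!r} in {path}")
        seen.add(rec.id)
        m = _CLASS_TOKEN.search(rec.description)
        if m:
            token = m.group(1)
            try:
                fc = FeatureClass(token)
            except ValueError:
                raise MisigError(f"invalid feature class: {token!r} in {path}") from None
        else:
            fc = FeatureClass.protein_coding
        genes.append(Gene(rec.id, str(rec.seq).upper(), fc))
    if not genes:
        raise MisigError(f"no genes: {path} has no FASTA records")
    return GeneSet(genome_id, tuple(genes))


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    """Write a gene set back to FASTA (inverse of :func:`read_gene_set`)."""
    records = []
    for g in gs.genes:
        desc = "" if g.feature_class is FeatureClass.protein_coding else f"[class={g.feature_class.value}]"
        records.append(SeqRecord(Seq(g.sequence), id=g.gene_id, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def filter_structural_rnas(gs: GeneSet) -> GeneSet:
    """Drop every gene that is not protein-coding (rRNA/tRNA/other).

    Idempotent; the input is unchanged.
    """
    kept = tuple(g for g in gs.genes if g.feature_class is FeatureClass.protein_coding)
    if not kept:
        raise MisigError(f"no protein-coding genes in genome {gs.genome_id!r}")
    if len(kept) == len(gs.genes):
        return gs
    return replace(gs, genes=kept)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["genome_id", "path", "role", "genus", "taxon_label", "is_proxy"]
_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f", ""}


def read_manifest(path: str | Path, check_paths: bool = True) -> list[ManifestEntry]:
    """Read and validate a cohort manifest (TSV).

    Relative genome paths are resolved against the manifest's directory.
    Exactly one ``primary_reference`` row is required.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise MisigError(f"parse error: manifest {path} missing columns {missing}")
    entries: list[ManifestEntry] = []
    for _, row in df.iterrows():
        try:
            role = Role(row["role"])
        except ValueError:
            raise MisigError(f"invalid role: {row['role']!r} in manifest {path}") from None
        token = str(row["is_proxy"]).strip().lower()
        if token in _TRUE_TOKENS:
            proxy = True
        elif token in _FALSE_TOKENS:
            proxy = False
        else:
            raise MisigError(f"parse error: is_proxy value {row['is_proxy']!r} in {path}")
        gpath = Path(row["path"])
        if not gpath.is_absolute():
            gpath = path.parent / gpath
        if check_paths and not gpath.exists():
            raise MisigError(f"parse error: genome path {gpath} does not exist")
        entries.append(
            ManifestEntry(
                genome_id=row["genome_id"],
                path=gpath,
                role=role,
                genus=row["genus"],
                taxon_label=row["taxon_label"],
                is_proxy=proxy,
            )
        )
    n_primary = sum(e.role is Role.primary_reference for e in entries)
    if n_primary != 1:
        raise MisigError(
            f"primary reference cardinality: manifest {path} has {n_primary} "
            "primary_reference rows (need exactly 1)"
        )
    return entries


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "genome_id": [e.genome_id for e in entries],
            "path": [str(e.path) for e in entries],
            "role": [e.role.value for e in entries],
            "genus": [e.genus for e in entries],
            "taxon_label": [e.taxon_label for e in entries],
            "is_proxy": [str(e.is_proxy).lower() for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = [
    "query_id",
    "subject_id",
    "ani_12",
    "ani_21",
    "ani_mean",
    "af_12",
    "af_21",
    "af_mean",
    "n_bbh",
]


def write_score_table(scores: Iterable[PairwiseScore], path: str | Path) -> None:
    """Write pairwise scores as TSV; undefined ANI fields are ``NA``."""
    rows = []
    for s in scores:
        rows.append(
            {
                "query_id": s.genome_a,
                "subject_id": s.genome_b,
                "ani_12": s.ani_12,
                "ani_21": s.ani_21,
                "ani_mean": s.ani_mean,
                "af_12": s.af_12,
                "af_21": s.af_21,
                "af_mean": s.af_mean,
                "n_bbh": s.n_bbh,
            }
        )
    df = pd.DataFrame(rows, columns=_SCORE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_score_table(path: str | Path) -> list[PairwiseScore]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except Exception as exc:  # malformed TSV
        raise MisigError(f"parse error: {path}: {exc}") from exc
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise MisigError(f"parse error: score table {path} missing columns {missing}")
    scores: list[PairwiseScore] = []
    for i, row in df.iterrows():
        line_no = i + 2  # 1-based, after the header
        try:
            ani_12 = None if pd.isna(row["ani_12"]) else float(row["ani_12"])
            ani_21 = None if pd.isna(row["ani_21"]) else float(row["ani_21"])
            n_bbh = int(row["n_bbh"])
            score = PairwiseScore(
                genome_a=str(row["query_id"]),
                genome_b=str(row["subject_id"]),
                ani_12=ani_12,
                ani_21=ani_21,
                af_12=float(row["af_12"]),
                af_21=float(row["af_21"]),
                n_bbh=n_bbh,
                defined=ani_12 is not None and ani_21 is not None,
            )
        except (TypeError, ValueError) as exc:
            raise MisigError(f"parse error: {path} line {line_no}: {exc}") from exc
        for val in (score.af_12, score.af_21):
            if math.isnan(val):
                raise MisigError(f"parse error: {path} line {line_no}: missing AF value")
        scores.append(score)
    return scores
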