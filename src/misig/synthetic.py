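"""Synthetic genomes and AF-ANI scatters with known ground truth.

Two generators make every stage testable without downloads:

* gene-level: a random reference gene set, plus derived genomes evolved from
  it with a controlled per-site substitution probability (Jukes-Cantor-like,
  uniform over the three alternative bases) and controlled gene retention, so
  the expected ANI is 100*(1-p) and the expected directional AF is the
  retained length fraction;
* scatter-level: (AF, ANI, role) points drawn from a Gompertz or logistic
  curve anchored near (1, 100), type-species points at low AF and non-type
  points at high AF with a configurable gap, Gaussian ANI noise, and the true
  inflection recorded alongside.

Everything is deterministic under the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import MisigError
from .io import (
    Gene,
    GeneSet,
    ManifestEntry,
    PairwiseScore,
    Role,
    write_gene_set,
    write_manifest,
)

__all__ = [
    "EvolveParams",
    "ScatterParams",
    "ScatterResult",
    "SyntheticCohort",
    "make_reference_genome",
    "evolve_genome",
    "make_genus_scatter",
    "scatter_to_scores",
    "make_synthetic_cohort",
    "write_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True, slots=True)
class EvolveParams:
    """Controls for deriving a genome from a reference gene set."""

    per_site_substitution_prob: float = 0.0
    gene_retention_fraction: float = 1.0
    n_novel_genes: int = 0
    indel_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("per_site_substitution_prob", "gene_retention_fraction", "indel_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MisigError(f"invalid params: {name}={v} not in [0, 1]")
        if self.n_novel_genes < 0:
            raise MisigError("invalid params: n_novel_genes < 0")


@dataclass(frozen=True, slots=True)
class ScatterParams:
    """Study-shaped AF-ANI scatter: a sigmoid trend rising to the (1, 100) anchor.

    Defaults put the true inflection at AF 0.35 with ANI ~74.7 (y0 + A/e for
    the Gompertz default), in the range the genus inflection points of real
    cohorts occupy.  The type cloud (AF below 0.32) and non-type cloud (AF
    above 0.38) are disjoint but abut the inflection region, the shape the
    published quadrant scatters show.
    """

    family: Literal["gompertz", "logistic"] = "gompertz"
    y0: float = 60.0
    amplitude: float = 40.0
    shape: float = 12.0            # Gompertz C / logistic K
    inflection_af: float = 0.35    # sets Gompertz B = exp(C*af) / logistic x0
    n_type: int = 30
    n_non_type: int = 30
    noise_sd_ani: float = 0.5
    af_range_type: tuple[float, float] = (0.02, 0.32)
    af_range_non_type: tuple[float, float] = (0.38, 0.98)
    boundary_gap: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_type < 1 or self.n_non_type < 1:
            raise MisigError("invalid params: n_type and n_non_type must be >= 1")
        if self.noise_sd_ani < 0:
            raise MisigError("invalid params: noise_sd_ani < 0")
        if self.family not in ("gompertz", "logistic"):
            raise MisigError(f"invalid params: family {self.family!r}")
        if (
            self.boundary_gap > 0
            and self.af_range_type[1] + self.boundary_gap > self.af_range_non_type[0]
        ):
            raise MisigError(
                "overlapping role ranges: type AF range must end at least "
                "boundary_gap below the non-type AF range"
            )

    def curve(self, af: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(af, dtype=np.float64)
        if self.family == "gompertz":
            b = np.exp(self.shape * self.inflection_af)
            return self.y0 + self.amplitude * np.exp(-b * np.exp(-self.shape * x))
        return self.y0 + self.amplitude / (1.0 + np.exp(-self.shape * (x - self.inflection_af)))

    @property
    def true_inflection(self) -> tuple[float, float]:
        if self.family == "gompertz":
            return (self.inflection_af, self.y0 + self.amplitude / np.e)
        return (self.inflection_af, self.y0 + self.amplitude / 2.0)


@dataclass(frozen=True, slots=True)
class ScatterResult:
    points: tuple[tuple[float, float, str], ...]  # (af, ani, role)
    truth: dict


@dataclass(frozen=True, slots=True)
class SyntheticCohort:
    reference: GeneSet
    members: tuple[tuple[GeneSet, Role], ...]  # excludes the reference


# ---------------------------------------------------------------------------
# Gene-level generators
# ---------------------------------------------------------------------------

def make_reference_genome(
    n_genes: int,
    length_range: tuple[int, int] = (300, 1500),
    gc: float = 0.5,
    seed: int = 0,
    genome_id: str = "ref",
) -> GeneSet:
    """Random i.i.d. gene set at the given GC content, deterministic under seed."""
    if n_genes < 1:
        raise MisigError("invalid params: n_genes must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise MisigError(f"invalid params: gc={gc} not in [0, 1]")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise MisigError(f"invalid params: length_range {length_range}")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    genes = []
    width = len(str(n_genes))
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[rng.choice(4, size=length, p=probs)])
        genes.append(Gene(f"{genome_id}_g{i:0{width}d}", seq))
    return GeneSet(genome_id, tuple(genes))


def _mutate(seq: str, p: float, indel_prob: float, rng: np.random.Generator) -> str:
    codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}.get(c, -1) for c in seq])
    out = codes.copy()
    if p > 0:
        hit = (rng.random(len(codes)) < p) & (codes >= 0)
        # substitute to one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=len(codes))
        out[hit] = (codes[hit] + shift[hit]) % 4
    chars = np.where(
        out >= 0, _BASES[np.clip(out, 0, 3)], np.array(list(seq))
    )
    if indel_prob > 0:
        pieces: list[str] = []
        for c in chars:
            r = rng.random()
            if r < indel_prob / 2:
                continue  # deletion
            pieces.append(c)
            if r > 1 - indel_prob / 2:
                pieces.append(str(_BASES[rng.integers(0, 4)]))  # insertion
        return "".join(pieces)
    return "".join(chars)


def evolve_genome(
    ref: GeneSet, params: EvolveParams, genome_id: str | None = None
) -> GeneSet:
    """Derive a genome: drop genes to the retention fraction, mutate the rest,
    append novel random genes.  Deterministic under ``params.seed``."""
    if not ref.genes:
        raise MisigError("no genes: reference gene set is empty")
    genome_id = genome_id or f"{ref.genome_id}_evolved"
    rng = np.random.default_rng(params.seed)
    n = len(ref.genes)
    k = int(round(params.gene_retention_fraction * n))
    if k == 0:
        raise MisigError("invalid params: gene retention yields zero genes")
    keep = np.sort(rng.choice(n, size=k, replace=False))
    genes: list[Gene] = []
    for i in keep:
        g = ref.genes[int(i)]
        genes.append(
            Gene(
                g.gene_id,
                _mutate(g.sequence, params.per_site_substitution_prob, params.indel_prob, rng),
                g.feature_class,
            )
        )
    lengths = [g.length for g in ref.genes]
    lo, hi = min(lengths), max(lengths)
    for j in range(params.n_novel_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        genes.append(Gene(f"{genome_id}_novel{j:03d}", seq))
    return GeneSet(genome_id, tuple(genes))


# ---------------------------------------------------------------------------
# Scatter generator
# ---------------------------------------------------------------------------

def make_genus_scatter(params: ScatterParams) -> ScatterResult:
    """Role-labelled (AF, ANI) points on the sigmoid trend plus the anchor.

    Type points are drawn uniformly in the low AF range, non-type in the high
    range; Gaussian noise is added to ANI.  The true inflection is recorded in
    ``truth`` so consumers never re-derive it.
    """
    rng = np.random.default_rng(params.seed)
    pts: list[tuple[float, float, str]] = []
    for role, n, (lo, hi) in (
        (Role.type_species, params.n_type, params.af_range_type),
        (Role.non_type, params.n_non_type, params.af_range_non_type),
    ):
        af = rng.uniform(lo, hi, size=n)
        ani = np.asarray(params.curve(af)) + rng.normal(0.0, params.noise_sd_ani, size=n)
        pts.extend((float(a), float(v), role.value) for a, v in zip(af, ani))
    pts.append((1.0, 100.0, Role.primary_reference.value))
    t_af, t_ani = params.true_inflection
    truth = {
        "family": params.family,
        "inflection_af": float(t_af),
        "inflection_ani": float(t_ani),
        "y0": params.y0,
        "amplitude": params.amplitude,
        "shape": params.shape,
        "noise_sd_ani": params.noise_sd_ani,
        "seed": params.seed,
    }
    return ScatterResult(points=tuple(pts), truth=truth)


def scatter_to_scores(
    result: ScatterResult,
) -> tuple[list[PairwiseScore], dict[str, Role]]:
    """Cast scatter points as PairwiseScore rows vs a nominal reference.

    The anchor point becomes the reference's self-comparison and is excluded
    from the returned score list (it is not a cohort member).
    """
    scores: list[PairwiseScore] = []
    roles: dict[str, Role] = {}
    i = 0
    for af, ani, role in result.points:
        if role == Role.primary_reference.value:
            continue
        gid = f"S{i:04d}"
        i += 1
        scores.append(
            PairwiseScore(
                genome_a=gid,
                genome_b="REF",
                ani_12=ani,
                ani_21=ani,
                af_12=af,
                af_21=af,
                n_bbh=10**6,
                defined=True,
            )
        )
        roles[gid] = Role(role)
    return scores, roles


# ---------------------------------------------------------------------------
# Whole-cohort generator (genomes + roles)
# ---------------------------------------------------------------------------

def make_synthetic_cohort(
    n_type: int = 4,
    n_non_type: int = 4,
    seed: int = 0,
    n_genes: int = 30,
    length_range: tuple[int, int] = (300, 600),
    gc: float = 0.5,
) -> SyntheticCohort:
    """A reference genome plus type-species and non-type relatives.

    Non-type genomes (same genus as the reference) evolve with low divergence
    and high gene retention; type species of other genera evolve with high
    divergence (ANI ~74-80) and low retention plus novel genes, reproducing
    the separated clouds the demarcation boundary relies on.
    """
    rng = np.random.default_rng(seed)
    ref = make_reference_genome(
        n_genes, length_range, gc, seed=int(rng.integers(2**31)), genome_id="G000_ref"
    )
    members: list[tuple[GeneSet, Role]] = []
    for i in range(n_type):
        retention = float(rng.uniform(0.25, 0.45))
        sub = float(rng.uniform(0.20, 0.26))
        novel = int(round((1 - retention) * n_genes))
        gs = evolve_genome(
            ref,
            EvolveParams(
                per_site_substitution_prob=sub,
                gene_retention_fraction=retention,
                n_novel_genes=novel,
                seed=int(rng.integers(2**31)),
            ),
            genome_id=f"G{i + 1:03d}_type",
        )
        members.append((gs, Role.type_species))
    for i in range(n_non_type):
        retention = float(rng.uniform(0.80, 0.95))
        sub = float(rng.uniform(0.03, 0.08))
        gs = evolve_genome(
            ref,
            EvolveParams(
                per_site_substitution_prob=sub,
                gene_retention_fraction=retention,
                n_novel_genes=int(rng.integers(0, 3)),
                seed=int(rng.integers(2**31)),
            ),
            genome_id=f"G{n_type + i + 1:03d}_nontype",
        )
        members.append((gs, Role.non_type))
    return SyntheticCohort(reference=ref, members=tuple(members))


def write_cohort(cohort: SyntheticCohort, outdir: str | Path, taxon_label: str = "SyntheticFamily") -> Path:
    """Write cohort FASTAs plus a manifest TSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    all_genomes = [(cohort.reference, Role.primary_reference)] + list(cohort.members)
    for gs, role in all_genomes:
        fasta = outdir / f"{gs.genome_id}.fna"
        write_gene_set(gs, fasta)
        genus = "Refgenus" if role is not Role.type_species else f"Genus_{gs.genome_id}"
        # store the bare filename: read_manifest resolves it against the
        # manifest's own directory, keeping the cohort relocatable
        entries.append(
            ManifestEntry(
                genome_id=gs.genome_id,
                path=Path(fasta.name),
                role=role,
                genus=genus,
                taxon_label=taxon_label,
            )
        )
    manifest = outdir / "manifest.tsv"
    write_manifest(entries, manifest)
    return manifest
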