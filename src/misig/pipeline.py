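"""End-to-end analysis: manifest -> scores -> boundary -> report.

``run_full_analysis`` wires the stages together: read the cohort manifest,
filter structural RNAs, score every genome against the primary reference,
derive the genus demarcation boundary from the type-species scores, classify
every genome, test type/non-type separation with the Wilcoxon rank-sum test
for AF and ANI, estimate the genus inflection point when enough points exist,
and summarise agreement with the annotated roles.  The report is a single
JSON-serialisable dict embedding the full configuration and seed so that a
rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .core import MisiConfig, compute_pairwise_score
from .demarcation import (
    agreement_summary,
    classify,
    compute_boundary,
    wilcoxon_rank_sum,
)
from .errors import MisigError
from .inflection import ANCHOR, InflectionConfig, estimate_genus_inflection
from .io import Role, filter_structural_rnas, read_gene_set, read_manifest

logger = logging.getLogger("misig")

__all__ = ["RunConfig", "run_full_analysis"]

_MIN_INFLECTION_SCORES = 6


@dataclass(frozen=True, slots=True)
class RunConfig:
    """Full run configuration; serialisable to a flat key=value text block."""

    misi: MisiConfig = field(default_factory=lambda: MisiConfig(prescreen_k=12))
    inflection: InflectionConfig = field(default_factory=InflectionConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_text(self) -> str:
        lines = []
        for section, obj in (("misi", self.misi), ("inflection", self.inflection)):
            for f in dataclasses.fields(obj):
                lines.append(f"{section}.{f.name}={getattr(obj, f.name)}")
        lines.append(f"seed={self.seed}")
        lines.append(f"log_level={self.log_level}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise MisigError(f"parse error: config line {line!r}")
            key, val = line.split("=", 1)
            raw[key.strip()] = val.strip()

        def build(section: str, klass):
            kwargs: dict[str, Any] = {}
            for f in dataclasses.fields(klass):
                key = f"{section}.{f.name}"
                if key not in raw:
                    continue
                val = raw[key]
                if val == "None":
                    kwargs[f.name] = None
                elif f.type in ("int", int):
                    kwargs[f.name] = int(val)
                elif f.type in ("float", float):
                    kwargs[f.name] = float(val)
                elif f.type.startswith("int | None") if isinstance(f.type, str) else False:
                    kwargs[f.name] = int(val)
                else:
                    try:
                        kwargs[f.name] = int(val)
                    except ValueError:
                        try:
                            kwargs[f.name] = float(val)
                        except ValueError:
                            kwargs[f.name] = val
            return klass(**kwargs)

        return cls(
            misi=build("misi", MisiConfig),
            inflection=build("inflection", InflectionConfig),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _score_row(s) -> dict:
    return {
        "genome_a": s.genome_a,
        "genome_b": s.genome_b,
        "ani_12": s.ani_12,
        "ani_21": s.ani_21,
        "ani_mean": s.ani_mean,
        "af_12": s.af_12,
        "af_21": s.af_21,
        "af_mean": s.af_mean,
        "n_bbh": s.n_bbh,
        "defined": s.defined,
    }


def run_full_analysis(manifest_path: str | Path, config: RunConfig | None = None) -> dict:
    """Run the whole workflow for one cohort; returns the JSON-ready report."""
    config = config or RunConfig()
    logging.basicConfig(level=config.log_level)
    entries = read_manifest(manifest_path)
    ref_entry = next(e for e in entries if e.role is Role.primary_reference)
    others = [e for e in entries if e.role is not Role.primary_reference]
    roles = {e.genome_id: e.role for e in entries}

    logger.info("reading %d genomes (reference: %s)", len(entries), ref_entry.genome_id)
    ref = filter_structural_rnas(read_gene_set(ref_entry.path, ref_entry.genome_id))
    scores = []
    for e in others:
        gs = filter_structural_rnas(read_gene_set(e.path, e.genome_id))
        scores.append(compute_pairwise_score(gs, ref, config.misi))

    type_scores = [s for s, e in zip(scores, others) if e.role is Role.type_species]
    warnings_list: list[str] = []
    if len(type_scores) < 2:
        msg = "insufficient type species: boundary derived from fewer than 2 type-species scores"
        logger.warning(msg)
        warnings_list.append(msg)

    try:
        boundary = compute_boundary(type_scores)
    except MisigError as exc:
        raise MisigError(f"boundary stage: {exc}") from exc

    classifications = []
    for s in scores:
        if s.ani_mean is None:
            msg = f"score undefined for {s.genome_a}; excluded from classification"
            logger.warning(msg)
            warnings_list.append(msg)
            continue
        classifications.append(classify(s, boundary))

    wilcoxon: dict[str, Any] = {}
    type_vals = [s for s, e in zip(scores, others) if e.role is Role.type_species and s.defined]
    non_type_vals = [s for s, e in zip(scores, others) if e.role is Role.non_type and s.defined]
    if type_vals and non_type_vals:
        for metric, getter in (("af", lambda s: s.af_mean), ("ani", lambda s: s.ani_mean)):
            res = wilcoxon_rank_sum(
                [getter(s) for s in type_vals], [getter(s) for s in non_type_vals]
            )
            wilcoxon[metric] = {
                "statistic_U": res.statistic_U,
                "p_two_sided": res.p_two_sided,
                "method": res.method,
                "n1": res.n1,
                "n2": res.n2,
            }
    else:
        wilcoxon["skipped"] = "need defined scores in both role groups"

    defined_points = [(s.af_mean, s.ani_mean) for s in scores if s.defined]
    if len(defined_points) >= _MIN_INFLECTION_SCORES:
        infl_cfg = dataclasses.replace(config.inflection, seed=config.seed)
        est = estimate_genus_inflection(defined_points + [ANCHOR], infl_cfg)
        inflection: dict[str, Any] = {
            "af_star": est.af_star,
            "ani_star": est.ani_star,
            "method": est.method,
            "r2_quartic": est.r2_quartic,
            "accepted": est.accepted,
            "ci95_af": est.ci95_af,
            "ci95_ani": est.ci95_ani,
            "ci99_af": est.ci99_af,
            "ci99_ani": est.ci99_ani,
            "sigmoid_inflections": est.sigmoid_inflections,
        }
    else:
        reason = (
            f"inflection skipped: {len(defined_points)} scores < {_MIN_INFLECTION_SCORES}"
        )
        logger.info(reason)
        inflection = {"skipped": reason}

    agreement = agreement_summary(classifications, roles) if classifications else None

    return {
        "tool": "misig",
        "version": __version__,
        "config": config.to_text(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "reference": ref_entry.genome_id,
        "scores": [_score_row(s) for s in scores],
        "boundary": {
            "af_boundary": boundary.af_boundary,
            "ani_boundary": boundary.ani_boundary,
            "setting_species_af": boundary.setting_species_af,
            "setting_species_ani": boundary.setting_species_ani,
            "joint": boundary.joint,
        },
        "classifications": [
            {"genome_id": c.genome_id, "zone": c.zone.value, "af": c.af, "ani": c.ani}
            for c in classifications
        ],
        "wilcoxon": wilcoxon,
        "inflection": inflection,
        "agreement": (
            None
            if agreement is None
            else {
                "n_total": agreement.n_total,
                "n_agree": agreement.n_agree,
                "n_disagree": agreement.n_disagree,
                "fraction_agree": agreement.fraction_agree,
                "disagreeing_ids": list(agreement.disagreeing_ids),
            }
        ),
        "warnings": warnings_list,
    }
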