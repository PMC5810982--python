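"""Pipeline orchestration: staged runs with provenance sidecar files.

Each stage (simulate, phase, spectrum, associate, hwe, select, hamming)
reads the artifacts of its predecessors from the run directory, writes its
own tables, and drops a ``<stage>.provenance.json`` recording inputs, the
seed, and the thresholds in force.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, catalog
from .association import (
    MultiplicityContext,
    UndefinedORError,
    adjust_pvalues,
    conditional_carrier_or,
)
from .haplotypes import CEH, Diplotype
from .io import (
    read_assignments_tsv,
    read_dataset,
    write_assignments_tsv,
    write_dataset,
)
from .phasing import phase_dataset, posterior_coverage_summary
from .selection import (
    classify_rare_frequent,
    estimate_conversion_selection,
    homozygote_excess_test,
)
from .similarity import carriage_by_distance
from .simulate import DatasetConfig, PoolRecipe, default_pool, generate_dataset
from .spectrum import build_spectrum, coverage_curve, rank_by_group, spectrum_summary

log = logging.getLogger("cehkit")

STAGES = ("simulate", "phase", "spectrum", "associate", "hwe", "select", "hamming")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for a pipeline run."""

    outdir: str = "cehkit_run"
    seed: int = 0
    stages: Sequence[str] = STAGES
    # simulation
    n: int = 2000
    n_rare: int = 300
    baseline_odds: float = 0.25
    n_regions: int = 14
    # thresholds
    min_copies: int = 50
    em_tol: float = 1e-6
    em_max_iter: int = 200
    alpha: float = 0.05
    exclusion_motif: str = catalog.RISK_MOTIF
    anchor: str = "a1"
    motif: str = "*~*~*~DRB1*15:01~DQB1*06:02~*"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _provenance(outdir: Path, stage: str, inputs: dict, config: RunConfig) -> None:
    payload = {
        "stage": stage,
        "inputs": inputs,
        "seed": config.seed,
        "thresholds": {
            "min_copies": config.min_copies,
            "em_tol": config.em_tol,
            "em_max_iter": config.em_max_iter,
            "alpha": config.alpha,
            "exclusion_motif": config.exclusion_motif,
        },
        "version": __version__,
    }
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(payload, indent=2))


def _load_phenotypes(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "phenotypes.tsv", sep="\t", dtype={"sample_id": str})


def _aligned(assignments, pheno: pd.DataFrame):
    """Diplotypes, phenotype array and regions aligned on shared sample ids."""
    pheno = pheno[pheno["sample_id"].isin(assignments)]
    dips = [assignments[s][0] for s in pheno["sample_id"]]
    y = (pheno["phenotype"] == "case").astype(int).to_numpy()
    return dips, y, list(pheno["region"])


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    pool = default_pool(n_rare=config.n_rare, seed=config.seed)
    ds = DatasetConfig(
        pool=pool, n=config.n, baseline_odds=config.baseline_odds,
        n_regions=config.n_regions,
    )
    records, truth = generate_dataset(ds, seed=config.seed)
    paths = write_dataset(records, outdir)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    log.info("simulate: wrote %d records", len(records))
    _provenance(outdir, "simulate", {"n": config.n, "n_rare": config.n_rare}, config)


def stage_phase(config: RunConfig, outdir: Path) -> None:
    records = read_dataset(
        outdir / "snps.vcf", outdir / "hla.tsv", outdir / "phenotypes.tsv"
    )
    result = phase_dataset(records, tol=config.em_tol, max_iter=config.em_max_iter)
    write_assignments_tsv(result.assignments, outdir / "assignments.tsv")
    freq_rows = [
        {"haplotype": h.key, "frequency": f}
        for h, f in sorted(result.ceh_frequencies().items(), key=lambda kv: -kv[1])
    ]
    pd.DataFrame(freq_rows).to_csv(outdir / "ceh_frequencies.tsv", sep="\t", index=False)
    coverage = posterior_coverage_summary(result.posteriors())
    summary = {
        "n_phased": len(result.assignments),
        "n_excluded": len(set(result.excluded)),
        "snp_em_converged": result.snp_result.converged,
        "extended_em_converged": result.extended_result.converged,
        "posterior_coverage": {str(k): v for k, v in coverage.items()},
    }
    (outdir / "phasing_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("phase: %d phased, %d excluded", summary["n_phased"], summary["n_excluded"])
    _provenance(outdir, "phase", {"records": len(records)}, config)


def stage_spectrum(config: RunConfig, outdir: Path) -> None:
    assignments = read_assignments_tsv(outdir / "assignments.tsv")
    pheno = _load_phenotypes(outdir)
    dips, _, regions = _aligned(assignments, pheno)
    spec = build_spectrum(dips)
    spec.to_frame().to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
    top_k = [k for k in (10, 25, 146, 810) if k <= spec.n_unique]
    summ = spectrum_summary(spec, top_k=top_k)
    payload = {
        "total_copies": summ.total_copies,
        "n_unique": summ.n_unique,
        "top_k": {str(k): {"copies": v[0], "percent": v[1]} for k, v in summ.top_k.items()},
        "multiplicity": {
            str(m): {
                "n_unique": v[0], "percent_unique": v[1],
                "copies": v[2], "percent_copies": v[3],
            }
            for m, v in summ.multiplicity.items()
        },
    }
    (outdir / "spectrum_summary.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame(coverage_curve(spec), columns=["n_unique", "cumulative_percent"]).to_csv(
        outdir / "coverage_curve.tsv", sep="\t", index=False
    )
    by_region = build_spectrum(dips, group_labels=regions)
    rank_by_group(by_region, global_spectrum=spec).to_csv(
        outdir / "region_ranks.tsv", sep="\t"
    )
    log.info("spectrum: %d unique CEHs over %d copies", spec.n_unique, spec.total_copies)
    _provenance(outdir, "spectrum", {"individuals": len(dips)}, config)


def stage_associate(config: RunConfig, outdir: Path) -> None:
    assignments = read_assignments_tsv(outdir / "assignments.tsv")
    pheno = _load_phenotypes(outdir)
    if "phenotype" not in pheno.columns:
        raise StageError("associate: phenotype column missing from phenotypes.tsv")
    dips, y, _ = _aligned(assignments, pheno)
    spec = build_spectrum(dips)
    rows = []
    for hap, count in spec.ranked():
        if count < config.min_copies:
            break
        try:
            res = conditional_carrier_or(
                dips, y, hap, copies=1, exclusion=config.exclusion_motif
            )
        except UndefinedORError:
            continue
        rows.append(
            {
                "haplotype": hap.key,
                "copies_in_cohort": count,
                "or": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        ctx = MultiplicityContext(m=len(df), method="benjamini-hochberg", alpha=config.alpha)
        df["p_bh"] = adjust_pvalues(df["p"].to_numpy(), ctx).adjusted
        bonf = MultiplicityContext(m=len(df), method="bonferroni", alpha=config.alpha)
        df["significant_bonferroni"] = adjust_pvalues(df["p"].to_numpy(), bonf).significant
    df.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    log.info("associate: tested %d haplotypes with >= %d copies", len(df), config.min_copies)
    _provenance(outdir, "associate", {"n_tested": len(df)}, config)


def stage_hwe(config: RunConfig, outdir: Path) -> None:
    assignments = read_assignments_tsv(outdir / "assignments.tsv")
    dips = [dip for dip, _ in assignments.values()]
    spec = build_spectrum(dips)
    observed = sum(1 for d in dips if d.is_homozygous)
    test = homozygote_excess_test(spec, observed, len(dips))
    (outdir / "hwe.json").write_text(json.dumps(asdict(test), indent=2))
    log.info("hwe: observed %d vs expected %.1f (z = %.2f)", test.observed,
             test.expected, test.z)
    _provenance(outdir, "hwe", {"individuals": len(dips)}, config)


def stage_select(config: RunConfig, outdir: Path) -> None:
    assignments = read_assignments_tsv(outdir / "assignments.tsv")
    dips = [dip for dip, _ in assignments.values()]
    spec = build_spectrum(dips)
    p_f, p_r = classify_rare_frequent(spec)
    rare = {h for h, c in spec.counts.items() if c == 1}
    n = len(dips)
    n_rr = sum(1 for d in dips if d.hap1 in rare and d.hap2 in rare)
    if p_r <= 0 or n_rr == 0:
        payload = {
            "p_frequent": p_f, "p_rare": p_r, "rare_rare_homozygotes": n_rr,
            "fit": None, "note": "no rare-rare homozygotes; model not estimable",
        }
    else:
        excess_rr = (n_rr / n) / p_r**2
        fit = estimate_conversion_selection(p_f, excess_rr, n=n)
        payload = {
            "p_frequent": p_f, "p_rare": p_r, "rare_rare_homozygotes": n_rr,
            "observed_excess_rr": excess_rr, "fit": asdict(fit),
        }
    (outdir / "selection.json").write_text(json.dumps(payload, indent=2))
    _provenance(outdir, "select", {"individuals": n}, config)


def stage_hamming(config: RunConfig, outdir: Path) -> None:
    assignments = read_assignments_tsv(outdir / "assignments.tsv")
    spec = build_spectrum([dip for dip, _ in assignments.values()])
    anchor = catalog.SNP_TAGS.get(config.anchor, config.anchor)
    profile = carriage_by_distance(spec.counts, anchor, config.motif)
    profile.by_distance.to_csv(outdir / "hamming_profile.tsv", sep="\t", index=False)
    profile.by_haplotype.to_csv(outdir / "hamming_haplotypes.tsv", sep="\t", index=False)
    _provenance(outdir, "hamming", {"anchor": anchor, "motif": config.motif}, config)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "phase": stage_phase,
    "spectrum": stage_spectrum,
    "associate": stage_associate,
    "hwe": stage_hwe,
    "select": stage_select,
    "hamming": stage_hamming,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages in canonical order; returns the run dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
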