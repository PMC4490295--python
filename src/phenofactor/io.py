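"""File formats, run configuration and the two-arm comparison workflow.

Genotypes travel as long-format TSV (subject_id, snp_id, genotype with
blank = missing) or as a minimal VCF dialect (biallelic, unphased GT
field only, ``./.`` missing).  Both yield the same internal
representation; in the VCF the minor allele is determined from the data
so that 2 always counts minor-allele homozygotes.  Item responses are
CSV with 0-based integer categories and a header of indicator labels.

``run_comparison`` ties the stages into the comparison workflow:
QC filter -> sum-score arm -> bi-factor arm (-> optional first-order
arm) -> effect-size table -> density summaries -> per-arm fit indices,
all seeded, with a manifest logging versions, seeds and row counts at
every filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    effect_size_density,
    fit_mimic,
    qc_filter,
    results_table,
    sum_score_association,
)
from .exceptions import ConfigError, DataError, PhenofactorError
from .measurement import MeasurementModelSpec, fit_dwls
from .polychoric import assemble_correlation_structure
from .sumscore import compute_sum_scores, describe_scores
from .synthetic import (
    GenotypeVector,
    ItemResponseMatrix,
    make_default_population,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one comparison run; YAML round trip is lossless
    and unknown keys are rejected by name."""

    out_dir: str = "phenofactor_out"
    items_path: str | None = None
    genotypes_path: str | None = None
    genotype_format: str = "tsv"          # tsv | vcf
    models: list[str] = field(default_factory=lambda: ["sum_score", "bifactor"])
    alpha: float = 0.05
    replicates: int = 1000
    seed: int = 0
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    complete_case: bool = True
    simulate: dict | None = None          # {n, maf, n_snps, effects: {...}} or snps list

    def to_yaml(self, path=None) -> str | None:
        payload = dataclasses.asdict(self)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigError("config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**payload)


# --------------------------------------------------------------------------
# genotype formats


def read_genotypes(path, format: str = "tsv") -> dict[str, GenotypeVector]:
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ConfigError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path) -> dict[str, GenotypeVector]:
    per_snp: dict[str, dict[str, float]] = {}
    subjects: list[str] = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["subject_id", "snp_id", "genotype"]:
            raise DataError(
                f"{path}: line 1: expected header subject_id\tsnp_id\tgenotype"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise DataError(f"{path}: line {lineno}: expected 3 fields")
            subj, snp, raw = parts
            if raw.strip() == "":
                val = float("nan")
            else:
                try:
                    val = float(int(raw))
                except ValueError:
                    raise DataError(
                        f"{path}: line {lineno}: genotype must be 0/1/2 or blank"
                    ) from None
                if val not in (0.0, 1.0, 2.0):
                    raise DataError(
                        f"{path}: line {lineno}: genotype must be 0/1/2 or blank"
                    )
            if subj not in seen:
                seen.add(subj)
                subjects.append(subj)
            per_snp.setdefault(snp, {})[subj] = val
    out = {}
    for snp, vals in per_snp.items():
        arr = np.array([vals.get(s, np.nan) for s in subjects])
        out[snp] = GenotypeVector(values=arr, snp_id=snp)
    return out


_GT_MAP = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0,
           "0|0": 0.0, "0|1": 1.0, "1|0": 1.0, "1|1": 2.0,
           "./.": float("nan"), ".|.": float("nan"), ".": float("nan")}


def _read_genotypes_vcf(path) -> dict[str, GenotypeVector]:
    out: dict[str, GenotypeVector] = {}
    n_samples = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise DataError(f"{path}: line {lineno}: VCF has no samples")
                n_samples = len(cols) - 9
                continue
            if n_samples is None:
                raise DataError(f"{path}: line {lineno}: record before #CHROM header")
            parts = line.split("\t")
            if len(parts) != 9 + n_samples:
                raise DataError(f"{path}: line {lineno}: expected "
                                f"{9 + n_samples} fields, got {len(parts)}")
            chrom, pos, snp_id, ref, alt, _qual, _filt, _info, fmt = parts[:9]
            if "," in alt:
                warnings.warn(f"{path}: line {lineno}: skipping multi-allelic "
                              f"record {snp_id}", stacklevel=2)
                continue
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise DataError(f"{path}: line {lineno}: record lacks GT field")
            gt_pos = fmt_keys.index("GT")
            vals = np.empty(n_samples)
            for i, cell in enumerate(parts[9:]):
                gt = cell.split(":")[gt_pos]
                if gt not in _GT_MAP:
                    raise DataError(f"{path}: line {lineno}: malformed GT {gt!r}")
                vals[i] = _GT_MAP[gt]
            # minor-allele convention: 2 = minor-allele homozygote
            ok = vals[~np.isnan(vals)]
            if ok.size and ok.mean() / 2.0 > 0.5:
                vals = 2.0 - vals
            out[snp_id if snp_id != "." else f"{chrom}:{pos}"] = GenotypeVector(
                values=vals, snp_id=snp_id
            )
    return out


def write_genotypes_tsv(genotypes: dict[str, GenotypeVector], path,
                        subjects: list[str] | None = None) -> None:
    any_g = next(iter(genotypes.values()))
    if subjects is None:
        subjects = [f"S{i:05d}" for i in range(any_g.n)]
    with open(path, "w") as fh:
        fh.write("subject_id\tsnp_id\tgenotype\n")
        for snp_id, g in genotypes.items():
            for subj, v in zip(subjects, g.values):
                cell = "" if np.isnan(v) else str(int(v))
                fh.write(f"{subj}\t{snp_id}\t{cell}\n")


def write_genotypes_vcf(genotypes: dict[str, GenotypeVector], path,
                        subjects: list[str] | None = None) -> None:
    any_g = next(iter(genotypes.values()))
    if subjects is None:
        subjects = [f"S{i:05d}" for i in range(any_g.n)]
    rev = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subjects) + "\n")
        for i, (snp_id, g) in enumerate(genotypes.items(), start=1):
            cells = [rev.get(v, "./.") for v in g.values]
            fh.write(f"1\t{1000 * i}\t{snp_id}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(cells) + "\n")


# --------------------------------------------------------------------------
# the comparison workflow

_METHOD_KINDS = {"bifactor": "bifactor", "first_order": "first_order"}


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = dict(config.simulate)
        n = int(sim.get("n", 1337))
        maf = float(sim.get("maf", 0.3))
        pop = make_default_population(n=n, maf=maf)
        snps = sim.get("snps")
        if snps is None:
            n_snps = int(sim.get("n_snps", 10))
            effects = sim.get("effects", {})
            snps = [{"snp_id": f"snp{i:03d}", "maf": maf,
                     "effects": effects.get(f"snp{i:03d}", {})}
                    for i in range(n_snps)]
        items, genotypes = simulate_cohort(pop, snps, seed=config.seed)
        return items, genotypes
    if config.items_path is None or config.genotypes_path is None:
        raise ConfigError("config needs either simulate or items/genotypes paths")
    items = ItemResponseMatrix.from_csv(config.items_path)
    genotypes = read_genotypes(config.genotypes_path, config.genotype_format)
    return items, genotypes


def run_comparison(config: RunConfig) -> dict:
    """Execute the full two-arm (optionally three-arm) comparison.

    Returns a manifest dict; all tables are written under
    ``config.out_dir``.  Any stage error aborts with the stage name
    while partial outputs are preserved on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "phenofactor", "version": __version__,
                      "seed": config.seed, "stages": []}

    def stage(name, counts):
        logger.info("stage=%s %s", name,
                    " ".join(f"{k}={v}" for k, v in counts.items()))
        manifest["stages"].append({"stage": name, **counts})

    current = "load"
    try:
        items, genotypes = _load_inputs(config)
        stage("load", {"n_subjects": items.n, "n_snps": len(genotypes),
                       "n_indicators": len(items.labels)})

        current = "qc"
        kept, qc_report = qc_filter(genotypes, config.call_rate_min,
                                    config.maf_min)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        stage("qc", {"n_in": len(genotypes), "n_kept": len(kept),
                     "n_dropped": len(genotypes) - len(kept)})

        current = "sum_scores"
        scores = compute_sum_scores(items)
        describe_scores(scores).to_csv(out / "sumscore_summary.tsv",
                                       sep="\t", index=False)
        stage("sum_scores", {"n_complete": scores.n_complete,
                             "n_excluded": scores.n_excluded})

        all_results = []
        fit_rows = []
        latent_kinds = [m for m in config.models if m in _METHOD_KINDS]

        current = "item_statistics"
        item_stats = None
        if latent_kinds:
            item_stats = assemble_correlation_structure(
                items, complete_case=config.complete_case)
            item_stats.to_tsv(out / "polychoric_matrix.tsv")
            stage("item_statistics", {"n": item_stats.n,
                                      "smoothed": int(item_stats.smoothed)})
            for kind in latent_kinds:
                spec = MeasurementModelSpec(kind=kind, dim_map=items.dim_map)
                fit = fit_dwls(item_stats, spec)
                fit_rows.append({
                    "model": kind, "chi_square": fit.chi_square, "df": fit.df,
                    "rmsea": fit.rmsea, "cfi": fit.cfi, "tli": fit.tli,
                    "converged": fit.converged, "n": fit.n,
                    "annotation": fit.indices_annotation(),
                })

        current = "association"
        for snp_id, g in kept.items():
            if "sum_score" in config.models:
                all_results.extend(sum_score_association(items, g))
            for kind in latent_kinds:
                spec = MeasurementModelSpec(kind=kind, dim_map=items.dim_map)
                res, _fit = fit_mimic(items, g, spec, item_stats=item_stats)
                all_results.extend(res)
        table = results_table(all_results)
        table.to_csv(out / "association_results.tsv", sep="\t", index=False)
        stage("association", {"n_rows": len(table), "n_snps": len(kept)})

        current = "densities"
        n_curves = 0
        if len(kept) >= 2:
            for method in sorted(table["method"].unique()):
                for phen in sorted(table.loc[table.method == method,
                                             "phenotype"].unique()):
                    vals = table.query("method == @method and phenotype == @phen"
                                       )["r2_percent"].to_numpy()
                    if vals.size < 2:
                        continue
                    grid, dens = effect_size_density(vals)
                    pd.DataFrame({"r2_percent": grid, "density": dens}).to_csv(
                        out / f"density_{method}_{phen}.tsv", sep="\t",
                        index=False)
                    n_curves += 1
        stage("densities", {"n_curves": n_curves})

        if fit_rows:
            pd.DataFrame(fit_rows).to_csv(out / "fit_indices.tsv", sep="\t",
                                          index=False)
    except PhenofactorError:
        logger.error("stage %s failed; partial outputs kept in %s", current, out)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
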