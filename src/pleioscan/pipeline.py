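"""End-to-end orchestration: file I/O, the full scan workflow, and the
power / type-I-error experiment comparing bivariate with univariate tests.

Genotype files use a text PLINK-style dialect:

* ``.map`` — four whitespace-separated columns per SNP: chromosome,
  SNP id, genetic distance (ignored, written as 0) and 1-based bp
  position.
* ``.ped`` — per sample: family id, individual id, four ignored columns
  (father, mother, sex, phenotype, written as 0), then two allele
  characters per SNP in .map order.  A ``0`` allele marks a missing call;
  missing genotypes are written ``0 0``.

Dosages are coded on the dataset-computed minor allele (ties at 0.5
resolved to the lexicographically smaller allele), so write-then-read
round-trips reproduce the dosage matrix exactly.

The supported envelope is desk scale — up to roughly 10^4 SNPs by 5*10^3
samples; genome-scale panels should be downsampled first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeDataset
from . import assoc, fngp, meta_ld, qc, strat, synthgen

logger = logging.getLogger(__name__)

#: The five trait pairs of the default scan: appendicular lean mass
#: against each femoral-neck geometry index.
DEFAULT_PAIRS = [("ALM", "W"), ("ALM", "CSA"), ("ALM", "CT"), ("ALM", "Z"), ("ALM", "BR")]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the abort message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# PLINK-style text I/O


def write_plink(G: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    prefix = Path(prefix)
    map_path = Path(str(prefix) + ".map")
    ped_path = Path(str(prefix) + ".ped")

    with open(map_path, "w") as fh:
        for _, s in G.snps.iterrows():
            fh.write(f"{s['chrom']}\t{s['snp_id']}\t0\t{s['pos']}\n")

    minor = G.snps["minor_allele"].to_numpy()
    major = G.snps["major_allele"].to_numpy()
    with open(ped_path, "w") as fh:
        for i in range(G.n_samples):
            sid = G.samples["sample_id"].iloc[i]
            fields = [str(sid), str(sid), "0", "0", "0", "0"]
            for j in range(G.n_snps):
                d = G.dosages[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2.0:
                    fields += [minor[j], minor[j]]
                elif d == 1.0:
                    # canonical order: the file never depends on which allele
                    # is designated minor, so round-trips are byte-stable
                    fields += sorted((minor[j], major[j]))
                else:
                    fields += [major[j], major[j]]
            fh.write("\t".join(fields) + "\n")
    return ped_path, map_path


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read ``<prefix>.ped`` / ``<prefix>.map`` into a dosage dataset.

    Dosages count the minor allele as observed in the file (ties broken
    lexicographically).  More than two observed alleles at a SNP is an
    error naming the SNP; a .ped line with the wrong column count is an
    error naming the line.
    """
    prefix = Path(prefix)
    map_rows = []
    with open(Path(str(prefix) + ".map")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f".map line {lineno}: expected 4 columns, got {len(parts)}")
            map_rows.append((int(parts[0]), parts[1], int(parts[3])))
    m = len(map_rows)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    expected_cols = 6 + 2 * m
    with open(Path(str(prefix) + ".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != expected_cols:
                raise ValueError(
                    f".ped line {lineno}: expected {expected_cols} columns, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])

    n = len(sample_ids)
    dosages = np.full((n, m), np.nan)
    snp_meta = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        observed = sorted({a for a in a1 + a2 if a != "0"})
        if len(observed) > 2:
            raise ValueError(f"SNP {snp_id}: more than two alleles observed: {observed}")
        if not observed:
            minor, major = "N", "N"
        elif len(observed) == 1:
            minor, major = observed[0], observed[0]
        else:
            counts = {al: 0 for al in observed}
            for a, b in zip(a1, a2):
                if a != "0":
                    counts[a] += 1
                    counts[b] += 1
            # less frequent allele is minor; exact tie -> lexicographic min
            minor = min(observed, key=lambda al: (counts[al], al))
            major = observed[0] if minor == observed[1] else observed[1]
        for i in range(n):
            if a1[i] == "0" or a2[i] == "0":
                continue
            dosages[i, j] = (a1[i] == minor) + (a2[i] == minor)
        snp_meta.append(
            {"snp_id": snp_id, "chrom": chrom, "pos": pos,
             "minor_allele": minor, "major_allele": major}
        )
    return GenotypeDataset(
        dosages=dosages,
        snps=pd.DataFrame(snp_meta),
        samples=pd.DataFrame({"sample_id": sample_ids}),
    )


# ---------------------------------------------------------------------------
# Run configuration and the full workflow


@dataclass
class RunConfig:
    """Everything a full run needs, serialisable to/from YAML.

    Either ``genotype_prefix``/``dxa_path`` point at input files, or
    ``synth`` describes a synthesis scenario (handled by
    :func:`synthesize_cohort`).
    """

    out_dir: str = "pleioscan_run"
    seed: int = 0
    genotype_prefix: str | None = None
    dxa_path: str | None = None
    synth: dict | None = None
    hwe_threshold: float = 0.01
    maf_threshold: float = 0.01
    hwe_method: str = "exact"
    n_pcs: int = 10
    pairs: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_PAIRS))
    report_thresholds: tuple[float, float] = (1e-5, 1e-4)
    ld_top_hits: int = 0  # 0 disables the region LD profile

    def validate(self) -> None:
        if self.synth is None and (self.genotype_prefix is None or self.dxa_path is None):
            raise ValueError("need either synth scenario or genotype_prefix + dxa_path")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        for t in self.report_thresholds:
            if not 0 < t < 1:
                raise ValueError("report thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.pairs = [tuple(p) for p in cfg.pairs]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def synthesize_cohort(
    scenario: dict, seed: int
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Build a cohort (genotypes + trait table) from a scenario dict.

    Scenario keys (all optional except ``n_samples``/``n_snps``):
    ``maf_range``, ``structure`` (n_subpops/fst/fractions), ``block``
    (``n_snps``/``maf`` for one LD block appended to the panel), and
    ``effects`` — a list of ``{snp_id, trait, beta}`` additive effects on
    named derived traits (beta in trait-SD units).
    """
    n = int(scenario["n_samples"])
    m = int(scenario["n_snps"])
    panel = synthgen.uniform_snp_panel(
        m, maf_range=tuple(scenario.get("maf_range", (0.05, 0.5))), seed=seed
    )
    block = scenario.get("block")
    if block:
        base_pos = panel[-1].pos
        panel += [
            synthgen.SNPSpec(
                f"blk{j}", 1, base_pos + (j + 1) * 4000,
                float(block.get("maf", 0.2)), block_id=1,
            )
            for j in range(int(block["n_snps"]))
        ]
    st = scenario.get("structure", {})
    structure = synthgen.StructureSpec(
        n_subpops=int(st.get("n_subpops", 1)),
        fst=float(st.get("fst", 0.0)),
        subpop_fractions=tuple(st["fractions"]) if "fractions" in st else None,
    )
    G = synthgen.simulate_genotypes(n, panel, structure, seed=seed + 1)

    dxa = synthgen.simulate_dxa_raw(n, seed=seed + 2)
    traits = fngp.compute_fngp_table(dxa)
    n_invalid = int((~traits["valid"]).sum())
    if n_invalid:
        logger.info("synthesize_cohort: %d invalid annulus records excluded", n_invalid)
    traits = inject_snp_effects(traits, G, scenario.get("effects", ()))
    return G, traits


def inject_snp_effects(
    traits: pd.DataFrame, G: GenotypeDataset, effects: Sequence[dict]
) -> pd.DataFrame:
    """Add additive per-minor-allele effects to named trait columns.

    Each effect dict has ``snp_id``, ``trait`` and ``beta`` (in SD units
    of that trait's current distribution) — ground truth for power and
    recovery experiments.
    """
    out = traits.copy()
    for e in effects:
        x = G.dosage(e["snp_id"]).copy()
        if np.isnan(x).any():
            x[np.isnan(x)] = np.nanmean(x)
        col = e["trait"]
        if col not in out.columns:
            raise ValueError(f"effect names unknown trait column: {col}")
        out[col] = out[col] + float(e["beta"]) * out[col].std(ddof=1) * x
    return out


def run_full_analysis(cfg: RunConfig) -> dict:
    """QC -> covariate adjustment -> bivariate/univariate scan -> reports.

    Returns a results bundle (dict) and writes TSV/JSON artifacts under
    ``cfg.out_dir``.  Every stage is logged with sample/SNP counts; any
    stage failure aborts with the stage name and a reproducible config
    dump.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out_dir / "config.yaml")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(name, f"{err} (config dumped to {out_dir/'config.yaml'})") from err

    # --- load or synthesise
    if cfg.synth is not None:
        G, traits = stage("synthesize", synthesize_cohort, cfg.synth, cfg.seed)
    else:
        G = stage("read_genotypes", read_plink, cfg.genotype_prefix)
        dxa = stage("read_dxa", pd.read_csv, cfg.dxa_path, sep="\t")
        traits = stage("derive_traits", fngp.compute_fngp_table, dxa)
    logger.info("input: %d samples x %d SNPs", G.n_samples, G.n_snps)

    valid = traits["valid"].to_numpy() if "valid" in traits.columns else np.ones(len(traits), bool)
    traits = traits.loc[valid].reset_index(drop=True)
    G = G.subset_samples(valid)

    # --- QC
    G_qc, report = stage("qc", qc.apply_qc, G, cfg.hwe_threshold, cfg.maf_threshold,
                         cfg.hwe_method)
    logger.info("qc: retained %d / %d SNPs", report.n_retained, report.n_total)
    if G_qc.n_snps == 0:
        raise PipelineError("scan", "no SNPs survive QC; nothing to scan")
    report.flags.to_csv(out_dir / "qc_flags.tsv", sep="\t", index=False)
    (out_dir / "qc_summary.json").write_text(report.to_json())

    # --- covariates: age, sex, genotype PCs
    trait_cols = [c for c in fngp.TRAIT_COLUMNS if c in traits.columns]
    covs = traits[["sample_id", "age", "sex"]].copy()
    terms = ["age", "sex"]
    if cfg.n_pcs > 0:
        pcs = stage("pca", strat.genotype_pca, G_qc, cfg.n_pcs)
        pcs.to_csv(out_dir / "pcs.tsv", sep="\t", index=False)
        covs = covs.merge(pcs, on="sample_id")
        terms += [f"pc_{i + 1}" for i in range(cfg.n_pcs)]
    adjusted = stage("adjust", strat.adjust_traits, traits, trait_cols, covs, terms)

    # --- association scan
    scan_traits = adjusted.data
    results = stage("scan", assoc.scan, G_qc, scan_traits, cfg.pairs)
    results.to_csv(out_dir / "scan_results.tsv", sep="\t", index=False)

    biv_cols = [f"p_biv_{a}_{b}" for a, b in cfg.pairs]
    tables = {}
    for thr in cfg.report_thresholds:
        mask = (results[biv_cols] < thr).any(axis=1)
        tbl = results.loc[mask].copy()
        tbl["min_p_biv"] = tbl[biv_cols].min(axis=1)
        tables[thr] = tbl.sort_values("min_p_biv").reset_index(drop=True)
        tables[thr].to_csv(out_dir / f"hits_p{thr:g}.tsv", sep="\t", index=False)

    # --- optional LD profile around the strongest hits
    ld_profile = None
    if cfg.ld_top_hits > 0:
        min_p = results[biv_cols].min(axis=1)
        top = results.loc[min_p.sort_values().index[: cfg.ld_top_hits], "snp_id"]
        ld_profile = stage(
            "ld", meta_ld.region_ld_profile, G_qc, list(top),
            pd.Series(min_p.to_numpy(), index=results["snp_id"]),
        )
        ld_profile[0].to_csv(out_dir / "ld_dprime.tsv", sep="\t")

    meta = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_samples": int(G.n_samples),
        "n_snps_input": int(report.n_total),
        "n_snps_retained": int(report.n_retained),
        "adjustment": adjusted.recipe["terms"],
        "pairs": [list(p) for p in cfg.pairs],
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2))

    return {
        "genotypes": G_qc,
        "qc_report": report,
        "adjusted_traits": adjusted,
        "results": results,
        "threshold_tables": tables,
        "ld_profile": ld_profile,
        "metadata": meta,
    }


def combine_cohorts(
    results_a: pd.DataFrame, results_b: pd.DataFrame, p_column: str
) -> pd.DataFrame:
    """Fisher-combine one p-value column across two cohorts' scan tables.

    Joins on ``snp_id`` (inner), so only SNPs tested in both cohorts get a
    combined p.
    """
    merged = results_a[["snp_id", p_column]].merge(
        results_b[["snp_id", p_column]], on="snp_id", suffixes=("_a", "_b")
    )
    combined = []
    for _, row in merged.iterrows():
        pa, pb = row[f"{p_column}_a"], row[f"{p_column}_b"]
        if np.isnan(pa) or np.isnan(pb):
            combined.append(np.nan)
        else:
            combined.append(meta_ld.fisher_combine([pa, pb]).p_combined)
    merged["p_combined"] = combined
    return merged


# ---------------------------------------------------------------------------
# Power / type-I-error experiment


@dataclass(frozen=True)
class PowerCell:
    """One scenario of the power grid: a single SNP with effects
    ``(beta1, beta2)`` (trait-SD units per minor allele) on a trait pair
    with the given residual correlation."""

    beta1: float
    beta2: float
    residual_corr: float = 0.5
    maf: float = 0.3
    n: int = 1000


def power_experiment(
    cells: Sequence[PowerCell],
    reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of the bivariate test and both
    univariate tests, per scenario cell.

    Each replicate simulates one SNP and a fresh trait pair, then applies
    all three tests at level ``alpha``.  Output rows carry the rejection
    rates with their Monte-Carlo standard errors ``sqrt(r(1-r)/reps)``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be positive")
    rows = []
    root = np.random.default_rng(seed)
    for cell in cells:
        rej = np.zeros(3)  # bivariate, univariate-1, univariate-2
        for _ in range(reps):
            s = int(root.integers(2**31 - 1))
            spec = [synthgen.SNPSpec("s0", 1, 1000, cell.maf)]
            G = synthgen.simulate_genotypes(cell.n, spec, seed=s)
            model = synthgen.PhenoModelSpec(
                residual_corr=cell.residual_corr, seed=s + 1
            )
            traits = synthgen.simulate_traits(
                G, [synthgen.EffectSpec("s0", cell.beta1, cell.beta2)], model
            )
            y = traits[["trait1", "trait2"]].to_numpy()
            x = G.dosages[:, 0]
            rej[0] += assoc.fit_bivariate(y, x).p < alpha
            rej[1] += assoc.fit_univariate(y[:, 0], x).p < alpha
            rej[2] += assoc.fit_univariate(y[:, 1], x).p < alpha
        rates = rej / reps
        se = np.sqrt(rates * (1 - rates) / reps)
        rows.append(
            {
                "beta1": cell.beta1, "beta2": cell.beta2,
                "residual_corr": cell.residual_corr, "maf": cell.maf,
                "n": cell.n, "reps": reps, "alpha": alpha,
                "power_bivariate": rates[0], "se_bivariate": se[0],
                "power_uni_trait1": rates[1], "se_uni_trait1": se[1],
                "power_uni_trait2": rates[2], "se_uni_trait2": se[2],
            }
        )
    return pd.DataFrame(rows)
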