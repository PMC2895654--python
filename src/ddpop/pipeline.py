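"""End-to-end orchestration: sequences in, one reproducible report out.

Stage order mirrors the analysis narrative: SNP calling -> diversity ->
linkage disequilibrium -> recombination -> clustering/geography -> (social
assays, when chimera data are present).  Every stage's parameters and seeds
come from a single :class:`RunConfig`; a failed stage is recorded in the
report and the remaining stages still run.  Fixed config + seeds give a
byte-identical summary JSON.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering_geo, diversity, linkage, recombination, seqio, social

__all__ = ["RunConfig", "run_full_analysis", "load_config"]

#: Genome size (bp) used for the expected genome-wide divergence summary.
DEFAULT_GENOME_SIZE = 34_000_000


@dataclass
class RunConfig:
    fragments: list[str]  # FASTA paths
    coords: str
    strains: str | None = None
    chimera: str | None = None  # CSV; social stage skipped when absent
    outdir: str = "ddpop_out"
    dense_chromosome: str = "chr4"
    maf: float = 0.10
    ld_permutations: int = 1000
    rho_permutations: int = 1000
    mantel_permutations: int = 1000
    social_permutations: int = 10_000
    bootstrap_replicates: int = 0  # 0 skips the bootstrap
    table_path: str | None = None  # precomputed two-locus table (npz)
    table_grid_points: int = 11
    table_grid_max: float = 100.0
    table_sims: int = 20_000
    genome_size: int = DEFAULT_GENOME_SIZE
    seed: int = 0
    figures: bool = False


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML run configuration (same field names as RunConfig)."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "fragments_dir" in raw:
        frag_dir = Path(raw.pop("fragments_dir"))
        raw["fragments"] = sorted(str(p) for p in frag_dir.glob("*.fasta"))
    return RunConfig(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else round(v, 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_full_analysis(config: RunConfig) -> dict:
    """Run every applicable stage; write summary.json and report.txt.

    Returns the report dict.  Stage failures are caught and recorded under
    ``errors`` with partial results retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(config).items() if k != "fragments"},
                    "n_fragment_files": len(config.fragments),
                    "errors": {}}
    state: dict = {}

    stages = [
        ("seqio", _stage_seqio),
        ("diversity", _stage_diversity),
        ("linkage", _stage_linkage),
        ("recombination", _stage_recombination),
        ("clustering_geo", _stage_clustering_geo),
        ("social", _stage_social),
    ]
    for name, fn in stages:
        try:
            section = fn(config, state)
            if section is not None:
                report[name] = section
        except Exception as exc:  # stage isolation: keep partial results
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            report.setdefault("tracebacks", {})[name] = traceback.format_exc(limit=3)

    payload = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(payload + "\n")
    _write_text_report(report, outdir / "report.txt")
    return report


def _stage_seqio(config: RunConfig, state: dict) -> dict:
    result = seqio.read_fragment_alignments(config.fragments, config.coords)
    call = seqio.call_snps(result.fragments)
    state["fragments"] = result.fragments
    state["matrix"] = call.matrix
    state["L"] = sum(f.length for f in result.fragments)
    seqio.write_snps(call.matrix, Path(config.outdir) / "snps.vcf")
    if config.strains:
        state["strain_table"] = seqio.read_strain_table(config.strains)
    return {
        "n_fragments": len(result.fragments),
        "rejected": result.rejected,
        "n_strains": call.matrix.n,
        "S": call.matrix.s,
        "L": state["L"],
        "n_multiallelic_excluded": call.n_multiallelic,
    }


def _groups_from_sites(state: dict) -> tuple[list[str], list[str]] | None:
    table = state.get("strain_table")
    matrix = state.get("matrix")
    if table is None or matrix is None:
        return None
    sites = table.sites()
    counts = sites.value_counts()
    if counts.iloc[0] < 2:
        return None
    dense = [s for s in matrix.strains if sites.get(s) == counts.index[0]]
    rest = [s for s in matrix.strains if s not in dense]
    if len(dense) < 2 or len(rest) < 2:
        return None
    return dense, rest


def _stage_diversity(config: RunConfig, state: dict) -> dict:
    matrix, L = state["matrix"], state["L"]
    summary = diversity.summarize(matrix, L)
    diffs = diversity.pairwise_differences(matrix)
    state["pairwise_diffs"] = diffs
    mean_d, sd_d = diffs.mean_sd()
    genome = diversity.genome_summaries(matrix.s, L, config.genome_size, summary.pi)
    section = {
        "S": summary.S,
        "L": summary.L,
        "n": summary.n,
        "theta_w": summary.theta_w,
        "pi": summary.pi,
        "tajima_d": summary.tajima_d,
        "mean_pairwise_diffs": mean_d,
        "sd_pairwise_diffs": sd_d,
        "snp_spacing_bp": genome.snp_spacing_bp,
        "expected_genome_diffs": genome.expected_genome_diffs,
    }
    groups = _groups_from_sites(state)
    if groups:
        dense, rest = groups
        section["fst_dense_vs_rest"] = diversity.hudson_fst(matrix, dense, rest)
        section["group_sizes"] = [len(dense), len(rest)]
        section["mean_diffs_dense"] = diffs.mean_sd(dense)[0]
        section["mean_diffs_rest"] = diffs.mean_sd(rest)[0]
    return section


def _stage_linkage(config: RunConfig, state: dict) -> dict:
    filtered = linkage.maf_filter(state["matrix"], config.maf)
    state["filtered"] = filtered
    pairs = linkage.pairwise_r2(filtered)
    chrom_of = filtered.chromosomes
    pairs["dense"] = np.array(
        [chrom_of[i] == config.dense_chromosome for i in pairs["i"]]
    ) & pairs["linked"]
    profile = linkage.ld_profile(pairs[pairs["dense"] | ~pairs["linked"]])
    dense_pairs = pairs[pairs["dense"] | ~pairs["linked"]]
    test = linkage.ld_decay_permutation_test(
        dense_pairs, config.ld_permutations, seed=config.seed + 1
    )
    state["pairs"] = pairs
    state["profile"] = profile
    if config.figures:
        _figure_ld(profile, Path(config.outdir) / "ld_decay.png")
    profile_rows = [
        {
            "left_bp": profile.edges[b],
            "right_bp": profile.edges[b + 1],
            "mean_r2": profile.mean_r2[b],
            "n_pairs": int(profile.counts[b]),
            "elevated": bool(profile.elevated[b]),
        }
        for b in range(len(profile.counts))
    ]
    pd.DataFrame(profile_rows).to_csv(
        Path(config.outdir) / "ld_profile.tsv", sep="\t", index=False
    )
    return {
        "maf_threshold": config.maf,
        "S_after_maf": filtered.s,
        "n_pairs": len(pairs),
        "baseline_mean_r2": profile.baseline_mean,
        "baseline_p80_r2": profile.baseline_p80,
        "n_unlinked_pairs": profile.n_unlinked,
        "decay_statistic": test.statistic,
        "decay_p_value": test.p_value,
    }


def _stage_recombination(config: RunConfig, state: dict) -> dict:
    dense_all = state["matrix"].on_chromosome(config.dense_chromosome)
    dense = state["filtered"].on_chromosome(config.dense_chromosome)
    rm = recombination.minimum_recombination_events(dense_all)
    span = float(dense_all.positions.max() - dense_all.positions.min())
    moment = recombination.wakeley_rho(dense_all, span)
    if config.table_path:
        table = recombination.TwoLocusTable.load(config.table_path)
    else:
        table = recombination.build_two_locus_table(
            dense.n,
            np.linspace(0.0, config.table_grid_max, config.table_grid_points),
            config.table_sims,
            seed=config.seed + 2,
        )
    estimate = recombination.composite_rho(dense, table, span)
    perm = recombination.likelihood_permutation_test(
        dense, table, span, config.rho_permutations, seed=config.seed + 3
    )
    if config.figures:
        _figure_likelihood(estimate, Path(config.outdir) / "rho_likelihood.png")
    pd.DataFrame(
        {"rho": estimate.grid, "log_composite_likelihood": estimate.log_likelihood}
    ).to_csv(Path(config.outdir) / "rho_curve.tsv", sep="\t", index=False)
    _write_rm_bed(rm, Path(config.outdir) / "rm_intervals.bed")
    return {
        "rm": rm.rm,
        "n_incompatible_pairs": rm.n_incompatible_pairs,
        "moment_rho": moment.rho,
        "moment_flag": moment.flag,
        "composite_rho": estimate.rho_hat,
        "composite_n_pairs": estimate.n_pairs,
        "composite_n_fallback": estimate.n_fallback,
        "rho_permutation_p": perm.p_value,
        "span_bp": span,
    }


def _stage_clustering_geo(config: RunConfig, state: dict) -> dict:
    concat = seqio.concatenate_alignments(state["fragments"])
    k2p = clustering_geo.k2p_distance(concat)
    section: dict = {"n_undefined_k2p_pairs": len(k2p.undefined_pairs)}
    if config.bootstrap_replicates > 0:
        tree = clustering_geo.bootstrap_support(
            concat, config.bootstrap_replicates, seed=config.seed + 4
        )
        section["bootstrap_replicates"] = config.bootstrap_replicates
        section["n_supported_99"] = sum(
            1 for v in tree.supports.values() if v > 99.0
        )
    else:
        tree = clustering_geo.neighbor_joining(k2p)
    newick = Path(config.outdir) / "nj_tree.nwk"
    tree.tree.write(str(newick))
    table = state.get("strain_table")
    if table is not None and not table.frame["latitude"].isna().any():
        sub = table.frame[table.frame["strain_id"].isin(state["matrix"].strains)]
        geo = clustering_geo.geographic_distances(seqio.StrainTable(sub.copy()))
        diffs = state["pairwise_diffs"]
        genetic = clustering_geo.SkbioDistanceMatrix(
            diffs.diffs.astype(float), ids=list(diffs.strains)
        )
        r, p = clustering_geo.mantel_test(
            genetic, geo, config.mantel_permutations, seed=config.seed + 5
        )
        section["mantel_r"] = r
        section["mantel_p"] = p
    return section


def _stage_social(config: RunConfig, state: dict) -> dict | None:
    if not config.chimera:
        return None  # no chimera data: section cleanly skipped
    frame = pd.read_csv(config.chimera)
    experiment = social.ChimeraExperiment(frame)
    stats = social.experiment_stats(experiment)
    section = {
        "n_pairs": len(stats),
        "mean_r_fb": float(np.mean([s.r_fb for s in stats])),
        "mean_abs_d": float(np.mean([s.abs_d for s in stats])),
        "per_pair": {
            s.pair: {"r_fb": s.r_fb, "abs_d": s.abs_d, "levene": s.levene}
            for s in stats
        },
    }
    table = state.get("strain_table")
    diffs = state.get("pairwise_diffs")
    if table is not None and diffs is not None:
        sites = table.sites()
        sym, div = {}, {}
        usable = []
        for s in stats:
            sub = experiment.frame[experiment.frame["pair"] == s.pair].iloc[0]
            a, b = sub.get("strain_a"), sub.get("strain_b")
            if a in sites.index and b in sites.index and a in diffs.strains and b in diffs.strains:
                sym[s.pair] = sites[a] == sites[b]
                div[s.pair] = float(
                    diffs.diffs[diffs.strains.index(a), diffs.strains.index(b)]
                )
                usable.append(s)
        if usable and len({sym[s.pair] for s in usable}) == 2:
            comparison = social.compare_groups(
                usable, sym, div, config.social_permutations, seed=config.seed + 6
            )
            section["sympatric_mean_r_fb"] = comparison.sympatric_mean
            section["allopatric_mean_r_fb"] = comparison.allopatric_mean
            section["sympatry_p_r_fb"] = comparison.p_value_r_fb
            section["sympatry_p_abs_d"] = comparison.p_value_abs_d
            section["regression_r2_r_fb"] = comparison.regression_r2_r_fb
            section["regression_r2_abs_d"] = comparison.regression_r2_abs_d
            section["median_divergence"] = comparison.median_divergence
    return section


def _write_rm_bed(rm: "recombination.RmResult", path: Path) -> None:
    lines = [
        f"{chrom}\t{left - 1}\t{right}\tbreakpoint_interval_{k + 1}"
        for k, (chrom, left, right) in enumerate(rm.intervals)
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _figure_ld(profile, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (profile.edges[:-1] + profile.edges[1:])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(centers / 1000.0, profile.mean_r2, "o-")
    if profile.baseline_mean is not None:
        ax.axhline(profile.baseline_mean, color="k", label="unlinked mean")
        ax.axhline(profile.baseline_p80, color="k", ls="--", label="unlinked 80th pct")
        ax.legend()
    ax.set_xscale("log")
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _figure_likelihood(estimate, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(estimate.grid, estimate.log_likelihood, "-")
    ax.axvline(estimate.rho_hat, color="r", ls=":", label=f"$\\hat\\rho$={estimate.rho_hat:g}")
    ax.set_xlabel(r"$\rho$")
    ax.set_ylabel("composite log likelihood")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["ddpop analysis report", "=" * 21, ""]
    for section, content in report.items():
        if section in ("config", "tracebacks"):
            continue
        lines.append(f"[{section}]")
        if isinstance(content, dict):
            for k, v in content.items():
                if isinstance(v, dict):
                    continue
                lines.append(f"  {k} = {v}")
        else:
            lines.append(f"  {content}")
        lines.append("")
    path.write_text("\n".join(lines))
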