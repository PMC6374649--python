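"""End-to-end orchestration: QC -> mating -> sibship -> spatial -> density
-> lineage -> IBD, from a single config with explicit seeding.

Every threshold lives in the config (never hard-coded in stages), every
random stage receives a seed derived deterministically from the master
seed, and identical config + seed yields byte-identical summary output.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nkio
from .genotypes import (
    AlleleFrequencies,
    MultilocusGenotype,
    augment_frequencies,
    estimate_allele_frequencies,
    genotype_counts,
)
from .mating import (
    QueenRecord,
    max_likely_frequency,
    run_simulation_1,
    run_simulation_2,
    summarize_mating,
)
from .qc import (
    LocusQCReport,
    correct_multiple_tests,
    estimate_null_allele_frequency,
    heterozygosities,
    hwe_test,
    ld_test,
    select_loci,
)
from .sibship import (
    ColonyPartition,
    SibshipPriors,
    estimate_sibship_priors,
    infer_queen_genotype,
    reconstruct_colonies,
)
from .simulate import (
    SimulationConfig,
    simulate_population,
    simulate_queen_sample,
    simulate_workers,
    apply_genotyping_error,
)
from .spatial import (
    ace_estimate,
    buffer_area,
    colony_foraging_distances,
    compare_sister_distances,
    foraging_summary,
    nest_density,
)
from .lineage import (
    ibd_regression,
    lineage_survival_rate,
    match_queens_across_years,
    pairwise_relatedness,
)

logger = logging.getLogger("nestkin")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class Thresholds:
    inclusion: float = 0.8
    null_allele: float = 0.1
    max_patrilines: int = 5
    queen_locus_confidence: float = 0.8
    gps_precision_m: float = 4.0
    rare_cutoff: int = 10
    alpha: float = 0.05
    lineage_match: float = 0.8
    sim2_tail: float = 0.05


@dataclass
class Reps:
    hwe: int = 10000
    ld: int = 2000
    sim1: int = 10000
    sim2: int = 1000
    ace_bootstrap: int = 1000


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "nestkin_out"
    synthetic: dict | None = None  # SimulationConfig overrides, or None
    inputs: dict | None = None  # genotypes/coordinates/queens/sperm paths
    stages: dict = field(
        default_factory=lambda: {
            s: True
            for s in ("qc", "mating", "sibship", "spatial", "density", "lineage", "ibd")
        }
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    reps: Reps = field(default_factory=Reps)
    error_rate: float = 0.0226
    mating_m: float | None = None  # override mean mating frequency for priors

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "reps" in kwargs:
            kwargs["reps"] = Reps(**kwargs["reps"])
        cfg = cls(**kwargs)
        stages = {
            s: True
            for s in ("qc", "mating", "sibship", "spatial", "density", "lineage", "ibd")
        }
        stages.update(cfg.stages or {})
        cfg.stages = stages
        return cfg


def _stage_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    names = [
        "simulate_population",
        "simulate_workers",
        "worker_error",
        "queen_error",
        "hwe",
        "ld",
        "sim1",
        "sim2",
        "sibship",
        "ace",
    ]
    return {name: int(rng.integers(2**31 - 1)) for name in names}


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


# ---------------------------------------------------------------------------


def _prepare_data(config: PipelineConfig, outdir: Path, seeds: dict[str, int]):
    """Load or simulate the worker/queen inputs; returns a data bundle."""
    if config.inputs is not None:
        paths = {k: Path(v) for k, v in config.inputs.items()}
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            raise PipelineError("inputs", f"missing input path(s): {missing}")
        workers, worker_years, rejected = nkio.read_genotype_table(paths["genotypes"])
        coords = nkio.read_coordinates(paths["coordinates"])
        queens_g, queen_years, q_rejected = nkio.read_genotype_table(paths["queens"])
        sperm = nkio.read_sperm_profiles(paths["sperm"])
        queens = [
            QueenRecord(g.id, g, sperm[g.id], year=queen_years.get(g.id))
            for g in queens_g
            if g.id in sperm
        ]
        return {
            "workers": workers,
            "worker_years": worker_years,
            "coords": coords,
            "queens": queens,
            "rejected": rejected + q_rejected,
            "truth": None,
            "sim_config": None,
        }

    sim_config = SimulationConfig(**(config.synthetic or {}))
    population = simulate_population(sim_config, seeds["simulate_population"])
    observations = simulate_workers(population, sim_config, seeds["simulate_workers"])
    observed = apply_genotyping_error(
        [w.genotype for w in observations],
        population.freqs,
        sim_config.mistyping_rate,
        sim_config.missing_rate,
        seeds["worker_error"],
    )
    worker_years = {w.worker_id: w.year for w in observations}
    coords = {w.worker_id: (w.x, w.y) for w in observations}
    _, _, q_colonies, sperm = simulate_queen_sample(
        sim_config,
        seeds["queen_error"],
        loci=population.loci,
        freqs=population.freqs,
    )
    observed_queens = apply_genotyping_error(
        [c.queen for c in q_colonies],
        population.freqs,
        sim_config.mistyping_rate,
        sim_config.missing_rate,
        seeds["queen_error"] // 2 + 1,
    )
    queens = [
        QueenRecord(c.colony_id, g, sperm[c.colony_id], year=c.year)
        for c, g in zip(q_colonies, observed_queens)
    ]
    nkio.write_genotype_table(observed, worker_years, outdir / "workers.csv")
    nkio.write_coordinates(coords, worker_years, outdir / "coordinates.csv")
    nkio.write_sperm_profiles(sperm, outdir / "sperm.csv")
    nkio.write_truth(observations, outdir / "truth.csv")
    return {
        "workers": observed,
        "worker_years": worker_years,
        "coords": coords,
        "queens": queens,
        "rejected": [],
        "truth": observations,
        "sim_config": sim_config,
    }


def _run_qc(data, config: PipelineConfig, seeds, outdir: Path):
    workers = data["workers"]
    years = sorted(set(data["worker_years"].values()))
    by_year = {
        y: [g for g in workers if data["worker_years"][g.id] == y] for y in years
    }
    loci = sorted({l for g in workers for l in g.calls})
    pooled_counts = {l: genotype_counts(workers, l) for l in loci}

    hwe_p: dict[str, dict[str, float | None]] = {l: {} for l in loci}
    raw_p: list[tuple[str, str, float]] = []
    for y in years:
        for l in loci:
            counts = genotype_counts(by_year[y], l)
            res = hwe_test(counts, reps=config.reps.hwe, seed=seeds["hwe"]) if len(
                {a for pair in counts for a in pair}
            ) >= 2 else None
            p = res.p_value if res is not None and res.testable else None
            hwe_p[l][str(y)] = p
            if p is not None:
                raw_p.append((l, str(y), p))
    corrected_alpha, _ = correct_multiple_tests(
        [p for _, _, p in raw_p], config.thresholds.alpha
    )
    hwe_sig = {
        l: {
            y: (p is not None and p < corrected_alpha)
            for y, p in hwe_p[l].items()
        }
        for l in loci
    }

    null_est = {}
    info = {}
    for l in loci:
        counts = pooled_counts[l]
        alleles = {a for pair in counts for a in pair}
        he, _ = heterozygosities(counts)
        info[l] = he
        null_est[l] = (
            estimate_null_allele_frequency(counts) if len(alleles) >= 2 else 0.0
        )

    ld_p: dict[frozenset[str], float | None] = {}
    pairs = [(a, b) for i, a in enumerate(loci) for b in loci[i + 1 :]]
    for a, b in pairs:
        ga, gb = [], []
        for g in workers:
            ca, cb = g.call(a), g.call(b)
            if ca is None or cb is None:
                continue
            ga.append(ca)
            gb.append(cb)
        if len(ga) < 10:
            ld_p[frozenset((a, b))] = None
            continue
        res = ld_test(ga, gb, reps=config.reps.ld, seed=seeds["ld"])
        ld_p[frozenset((a, b))] = res.p_value if res.testable else None
    usable = [p for p in ld_p.values() if p is not None]
    ld_alpha, _ = correct_multiple_tests(usable, config.thresholds.alpha) if usable else (
        0.0,
        [],
    )
    ld_sig = {pair for pair, p in ld_p.items() if p is not None and p < ld_alpha}

    report = LocusQCReport(
        loci=loci,
        hwe_significant=hwe_sig,
        null_estimates=null_est,
        informativeness=info,
        ld_significant=ld_sig,
        hwe_p=hwe_p,
        ld_p=ld_p,
        null_threshold=config.thresholds.null_allele,
    )
    retained = select_loci(report)
    report.to_frame().to_csv(outdir / "qc_report.csv", index=False)
    return {
        "retained_loci": retained,
        "n_loci": len(loci),
        "hwe_corrected_alpha": corrected_alpha,
        "ld_corrected_alpha": ld_alpha,
        "report": report,
    }


def _run_mating(data, config: PipelineConfig, seeds, outdir: Path):
    queens = data["queens"]
    if not queens:
        raise PipelineError("mating", "no queens with sperm profiles")
    freqs = estimate_allele_frequencies(data["workers"])
    # queens may carry alleles the worker sample missed: rare-allele floor
    freqs = augment_frequencies(freqs, [q.genotype for q in queens])
    sim1 = run_simulation_1(queens, freqs, reps=config.reps.sim1, seed=seeds["sim1"])
    summary = summarize_mating(queens, sim1)
    matrix = run_simulation_2(
        queens,
        freqs,
        sim1.critical_value,
        reps=config.reps.sim2,
        seed=seeds["sim2"],
    )
    max_likely = max_likely_frequency(
        matrix, summary.max_observed, tail=config.thresholds.sim2_tail
    )
    pd.DataFrame(
        [
            {"queen_id": qid, **vals}
            for qid, vals in summary.per_queen.items()
        ]
    ).to_csv(outdir / "mating_per_queen.csv", index=False)
    pd.DataFrame(
        matrix.probs,
        index=[f"true_{t}" for t in matrix.true_counts],
        columns=[f"obs_{k}" for k in range(matrix.probs.shape[1])],
    ).to_csv(outdir / "miscount_matrix.csv")
    return {
        "mean_minimum_mating_frequency": summary.mean_min_mating_frequency,
        "percent_monandrous": summary.percent_monandrous,
        "critical_value": sim1.critical_value,
        "mean_expected_match_rate": sim1.mean_rate,
        "sd_expected_match_rate": sim1.sd_rate,
        "max_observed_mates": summary.max_observed,
        "max_likely_mating_frequency": max_likely,
        "summary_obj": summary,
    }


def _run_sibship(data, config, seeds, outdir, retained_loci, mating_mean):
    workers = data["workers"]
    freqs = estimate_allele_frequencies(data["workers"])
    years = sorted(set(data["worker_years"].values()))
    m = config.mating_m if config.mating_m is not None else max(mating_mean, 1.0)
    partitions: dict[int, ColonyPartition] = {}
    priors_used: dict[str, dict] = {}
    for y in years:
        group = [g for g in workers if data["worker_years"][g.id] == y]
        first = reconstruct_colonies(
            group,
            freqs,
            priors=None,
            min_inclusion=config.thresholds.inclusion,
            error_rate=config.error_rate,
            seed=seeds["sibship"],
            year=y,
            loci=retained_loci,
            max_patrilines=config.thresholds.max_patrilines,
            queen_confidence=config.thresholds.queen_locus_confidence,
        )
        priors = estimate_sibship_priors(first, m)
        partition = reconstruct_colonies(
            group,
            freqs,
            priors=priors,
            min_inclusion=config.thresholds.inclusion,
            error_rate=config.error_rate,
            seed=seeds["sibship"],
            year=y,
            loci=retained_loci,
            max_patrilines=config.thresholds.max_patrilines,
            queen_confidence=config.thresholds.queen_locus_confidence,
        )
        partitions[y] = partition
        priors_used[str(y)] = {"m": priors.m, "n": priors.n}
    frame = pd.concat([p.frame for p in partitions.values()], ignore_index=True)
    frame.to_csv(outdir / "partition.csv", index=False)
    info = pd.concat([p.colony_info for p in partitions.values()], ignore_index=True)
    info.to_csv(outdir / "colonies.csv", index=False)
    return {
        "partitions": partitions,
        "priors": priors_used,
        "colonies_detected": {
            str(y): int(len(partitions[y].colonies())) for y in years
        },
        "accepted_colonies": {
            str(y): int(len(partitions[y].accepted_colonies())) for y in years
        },
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the summary dict (also written
    to ``summary.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed}

    data = _prepare_data(config, outdir, seeds)
    summary["n_workers"] = len(data["workers"])
    summary["n_queens"] = len(data["queens"])
    summary["rejected_records"] = data["rejected"]

    retained_loci = sorted({l for g in data["workers"] for l in g.calls})
    if config.stages.get("qc"):
        try:
            qc = _run_qc(data, config, seeds, outdir)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("qc", str(exc)) from exc
        retained_loci = qc["retained_loci"]
        summary["qc"] = {
            "n_loci": qc["n_loci"],
            "retained_loci": retained_loci,
            "hwe_corrected_alpha": qc["hwe_corrected_alpha"],
            "ld_corrected_alpha": qc["ld_corrected_alpha"],
        }

    mating_mean = 1.0
    if config.stages.get("mating"):
        try:
            mating = _run_mating(data, config, seeds, outdir)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("mating", str(exc)) from exc
        mating_mean = mating["mean_minimum_mating_frequency"]
        summary["mating"] = {
            k: v for k, v in mating.items() if k != "summary_obj"
        }

    partitions = None
    if config.stages.get("sibship"):
        try:
            sib = _run_sibship(data, config, seeds, outdir, retained_loci, mating_mean)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("sibship", str(exc)) from exc
        partitions = sib["partitions"]
        summary["sibship"] = {
            "priors": sib["priors"],
            "colonies_detected": sib["colonies_detected"],
            "accepted_colonies": sib["accepted_colonies"],
        }

    nests_by_year = {}
    mean_foraging = None
    if config.stages.get("spatial"):
        if partitions is None:
            raise PipelineError("spatial", "requires the sibship stage")
        coords = data["coords"]
        spatial_summary = {}
        all_nests = []
        for y, partition in partitions.items():
            members = {
                c: partition.members(c) for c in partition.accepted_colonies()
            }
            nests, excluded = colony_foraging_distances(
                members, coords, config.thresholds.gps_precision_m
            )
            nests_by_year[y] = nests
            all_nests.extend(nests)
            if excluded:
                logger.info("year %s: %d colonies excluded by the 4 m rule", y, len(excluded))
        if not all_nests:
            raise PipelineError("spatial", "no colonies passed the location-spread rule")
        fs = foraging_summary(all_nests)
        mean_foraging = fs["mean_colony_foraging_distance_m"]
        spatial_summary.update(fs)
        try:
            frame = pd.concat([p.frame for p in partitions.values()])
            spatial_summary["sister_distance_test"] = compare_sister_distances(
                frame, coords
            )
        except ValueError as exc:
            spatial_summary["sister_distance_test"] = {"error": str(exc)}
        pd.DataFrame(
            [
                {
                    "colony_id": n.colony_id,
                    "year": y,
                    "x_m": n.x,
                    "y_m": n.y,
                    "foraging_distance_m": n.foraging_distance,
                    "n_workers": n.n_workers,
                }
                for y, nests in nests_by_year.items()
                for n in nests
            ]
        ).to_csv(outdir / "nests.csv", index=False)
        pd.DataFrame(
            [
                {"colony_id": n.colony_id, "year": y, "distance_m": d}
                for y, nests in nests_by_year.items()
                for n in nests
                for d in n.worker_distances
            ]
        ).to_csv(outdir / "worker_distances.csv", index=False)
        summary["spatial"] = spatial_summary

    if config.stages.get("density"):
        if partitions is None:
            raise PipelineError("density", "requires the sibship stage")
        if mean_foraging is None:
            raise PipelineError("density", "requires the spatial stage")
        sim_cfg = data["sim_config"]
        side = sim_cfg.arena_side_m if sim_cfg is not None else 2000.0
        core_ha = side * side / 1e4
        buf_ha = buffer_area(side, mean_foraging)
        density_summary = {}
        for y, partition in partitions.items():
            abundances = partition.frame.groupby("colony_id").size().to_numpy()
            ace = ace_estimate(
                abundances,
                rare_cutoff=config.thresholds.rare_cutoff,
                bootstrap_reps=config.reps.ace_bootstrap,
                seed=seeds["ace"],
            )
            dens = nest_density(ace, core_ha, buf_ha, year=y)
            density_summary[str(y)] = {
                "colonies_detected": ace.s_obs,
                "estimated_colonies": ace.estimate,
                "se": ace.se,
                "ci95": list(ace.ci95) if ace.ci95 else None,
                "density_per_ha": dens.density,
                "completeness": dens.completeness,
                "core_area_ha": core_ha,
                "buffer_area_ha": buf_ha,
            }
        (outdir / "density.json").write_text(
            json.dumps(_round_floats(density_summary), indent=2, sort_keys=True)
        )
        summary["density"] = density_summary

    queens_inferred = {}
    if config.stages.get("lineage") or config.stages.get("ibd"):
        if partitions is None:
            raise PipelineError("lineage", "requires the sibship stage")
        freqs = estimate_allele_frequencies(data["workers"])
        from .sibship import PairwiseKin

        kin = PairwiseKin(freqs, retained_loci, config.error_rate)
        for y, partition in partitions.items():
            lookup = {g.id: g for g in data["workers"]}
            pat_of = dict(
                zip(partition.frame["worker_id"], partition.frame["patriline"])
            )
            queens_inferred[y] = [
                infer_queen_genotype(
                    [lookup[w] for w in partition.members(c)],
                    freqs,
                    config.error_rate,
                    colony_id=c,
                    min_confidence=config.thresholds.queen_locus_confidence,
                    kin=kin,
                    patrilines=pat_of,
                )
                for c in partition.colonies()
            ]

    if config.stages.get("lineage"):
        years = sorted(partitions)
        if len(years) < 2:
            raise PipelineError("lineage", "needs two sampling years")
        y1, y2 = years[0], years[-1]
        freqs = estimate_allele_frequencies(data["workers"])
        lookup = {g.id: g for g in data["workers"]}
        matches, unmatched = match_queens_across_years(
            queens_inferred[y2],
            partitions[y1].frame,
            lookup,
            freqs,
            threshold=config.thresholds.lineage_match,
            error_rate=config.error_rate,
            loci=retained_loci,
        )
        n1 = len(partitions[y1].colonies())
        rate = lineage_survival_rate(matches, n1)
        pd.DataFrame(
            [
                {
                    "queen_colony": m.queen_colony,
                    "matched_colony": m.matched_colony,
                    "probability": m.probability,
                }
                for m in matches
            ]
        ).to_csv(outdir / "lineage_matches.csv", index=False)
        summary["lineage"] = {
            "n_matches": len(matches),
            "n_colonies_earlier": n1,
            "n_unmatched_queens": len(unmatched),
            "survival_rate": rate,
        }

    if config.stages.get("ibd"):
        if not nests_by_year:
            raise PipelineError("ibd", "requires the spatial stage")
        freqs = estimate_allele_frequencies(data["workers"])
        positions = {
            n.colony_id: (n.x, n.y)
            for nests in nests_by_year.values()
            for n in nests
        }
        queens = [
            q
            for qs in queens_inferred.values()
            for q in qs
            if q.colony_id in positions and q.genotype.typed_loci()
        ]
        if len(queens) < 3:
            raise PipelineError("ibd", "fewer than three queens with confident loci")
        matrix = pairwise_relatedness(queens, freqs, positions)
        matrix.pairs_frame().to_csv(outdir / "relatedness_pairs.csv", index=False)
        try:
            reg = ibd_regression(matrix)
            summary["ibd"] = {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "f_statistic": reg.f_statistic,
                "df": list(reg.df),
                "p_value": reg.p_value,
                "r_squared": reg.r_squared,
                "n_pairs": reg.n_pairs,
            }
        except ValueError as exc:
            raise PipelineError("ibd", str(exc)) from exc

    clean = _round_floats(summary)
    (outdir / "summary.json").write_text(json.dumps(clean, indent=2, sort_keys=True))
    return clean
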