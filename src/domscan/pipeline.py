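"""End-to-end orchestration: generate/load -> QC -> stats -> scans -> LD.

One YAML config drives a full reproducible run; a single master seed spawns
per-stage substreams so one integer reproduces everything. The manifest
records the config snapshot, seeds, stage timings, record counts and SHA-256
digests of every output file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, ld, popstats, qc, scan
from .datamodel import PairConfig
from .synth import SynthSpec, generate_pair


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    stages: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, records: int) -> None:
        self.stages.append(
            {"stage": name, "seconds": round(seconds, 4), "records": records}
        )

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "stages": self.stages,
                    "outputs": self.outputs,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_full_scan(config: dict | str | Path, outdir: str | Path | None = None) -> RunManifest:
    """Run the whole pipeline from a config mapping or YAML path.

    Config keys: ``pair`` (PairConfig fields), ``synth`` (SynthSpec fields;
    omit and give ``genotypes``/``map`` paths to load data instead), ``scan``
    (``nperm``, ``grid_points``), ``ld`` (``max_distance``), ``outdir``,
    ``seed``. Validation happens before any stage runs.
    """
    cfg = _load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "domscan_run"))
    master_seed = int(cfg.get("seed", 0))
    pair_cfg = PairConfig.from_mapping({**cfg.get("pair", {}), "seed": master_seed})
    scan_cfg = dict(cfg.get("scan", {}))
    ld_cfg = dict(cfg.get("ld", {}))
    nperm = int(scan_cfg.get("nperm", pair_cfg.perm_reps))
    if nperm < 1:
        raise ValueError("scan.nperm must be >= 1")
    grid_points = int(scan_cfg.get("grid_points", scan.GRID_POINTS))
    max_distance = float(ld_cfg.get("max_distance", 50.0))

    ss = np.random.SeedSequence(master_seed)
    sub = ss.spawn(4)
    seeds = {
        "master": master_seed,
        "synth": int(sub[0].generate_state(1)[0] % 2**31),
        "bootstrap": int(sub[1].generate_state(1)[0] % 2**31),
        "scan_fst": int(sub[2].generate_state(1)[0] % 2**31),
        "scan_lnrh": int(sub[3].generate_state(1)[0] % 2**31),
    }
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seeds=seeds)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                self.seconds = time.perf_counter() - self.t0
                return False

        return _Timer()

    # ---------------- inputs ----------------
    with stage("input") as t:
        if "synth" in cfg:
            spec = SynthSpec(
                **{
                    **cfg["synth"],
                    "seed": seeds["synth"],
                    "wild_label": pair_cfg.wild_label,
                    "dom_label": pair_cfg.domesticated_label,
                }
            )
            panel, lmap, truth = generate_pair(spec)
            truth_path = outdir / "truth.tsv"
            pd.Series(truth.labels, name="label").rename_axis("locus_id").to_csv(
                truth_path, sep="\t"
            )
            manifest.add_output(truth_path)
        else:
            panel, lmap = io.read_panel(cfg["genotypes"], cfg.get("map"))
        geno_path, map_path = io.write_panel(panel, lmap, outdir / "input")
        manifest.add_output(geno_path)
        manifest.add_output(map_path)
    manifest.add_stage("input", t.seconds, panel.n_loci)

    # ---------------- qc ----------------
    with stage("qc") as t:
        qcres = qc.apply_filters(panel, lmap, pair_cfg)
        report_path = outdir / "filter_report.tsv"
        qcres.report.to_frame().to_csv(report_path, sep="\t")
        manifest.add_output(report_path)
    manifest.add_stage("qc", t.seconds, qcres.common.n_loci)

    wild, dom = pair_cfg.wild_label, pair_cfg.domesticated_label

    # ---------------- stats ----------------
    with stage("stats") as t:
        flat, fst, ln = popstats.locus_stat_table(
            qcres.common, wild, dom, n_boot=pair_cfg.bootstrap_reps,
            seed=seeds["bootstrap"],
        )
        summary = popstats.pair_summary(
            qcres.common, wild, dom, t=pair_cfg.generations_since_split,
            n_boot=pair_cfg.bootstrap_reps, seed=seeds["bootstrap"],
        )
        stats_path = outdir / "locus_stats.tsv"
        flat.to_csv(stats_path, sep="\t")
        summary_path = outdir / "pair_summary.tsv"
        summary.to_frame().to_csv(summary_path, sep="\t")
        outliers = scan.lnrh_outliers(flat["lnrh_z"], pair_cfg.lnrh_z)
        outlier_path = outdir / "lnrh_outliers.tsv"
        outliers.to_csv(outlier_path, sep="\t")
        for p in (stats_path, summary_path, outlier_path):
            manifest.add_output(p)
    manifest.add_stage("stats", t.seconds, len(flat))

    # ---------------- scans ----------------
    mapped_ids = [lid for lid in qcres.mapped.locus_ids]
    mapped_map = lmap.subset(mapped_ids) if lmap is not None else None
    scan_results = {}
    for stat_name, tails, seed_key in (
        ("fst", "upper", "scan_fst"),
        ("lnrh", "two", "scan_lnrh"),
    ):
        with stage(f"scan_{stat_name}") as t:
            col = "theta" if stat_name == "fst" else "lnrh_z"
            values = flat.loc[flat.index.isin(mapped_ids), col]
            track = scan.scan_genome(
                values,
                mapped_map,
                nperm=nperm,
                tails=tails,
                region_alpha=pair_cfg.region_alpha,
                seed=seeds[seed_key],
                grid_points=grid_points,
            )
            track_path = outdir / f"scan_{stat_name}_track.tsv"
            track.to_frame().to_csv(track_path, sep="\t", index=False)
            region_path = outdir / f"scan_{stat_name}_regions.tsv"
            track.regions.to_csv(region_path, sep="\t", index=False)
            manifest.add_output(track_path)
            manifest.add_output(region_path)
            scan_results[stat_name] = track
        manifest.add_stage(f"scan_{stat_name}", t.seconds, len(track.regions))

    # ---------------- ld ----------------
    with stage("ld") as t:
        ld_rows = 0
        decay = {}
        for label in (wild, dom):
            pop_panel = qcres.mapped.population_panel(label)
            pairs = ld.pairwise_ld(pop_panel, mapped_map, max_distance=max_distance)
            path = outdir / f"ld_pairs_{label}.tsv"
            pairs.to_csv(path, sep="\t", index=False)
            manifest.add_output(path)
            ld_rows += len(pairs)
            n_chrom = 2 * pop_panel.n_individuals
            try:
                fit = ld.fit_decay(pairs, n_chromosomes=n_chrom)
                decay[label] = {
                    "rho_per_cm": fit.rho_per_cm,
                    "half_decay_cm": fit.half_decay,
                }
            except ValueError as exc:
                decay[label] = {"error": str(exc)}
    manifest.add_stage("ld", t.seconds, ld_rows)

    # ---------------- report ----------------
    with stage("report") as t:
        half_decays = [
            d["half_decay_cm"] for d in decay.values() if "half_decay_cm" in d
        ]
        report = {
            "retention": {
                pop: counts
                for pop, counts in qcres.report.per_population.items()
            },
            "common": qcres.report.common,
            "mapped": qcres.report.mapped,
            "fst": summary.fst,
            "fst_ci": list(summary.fst_ci),
            "fis": {p: r.f for p, r in summary.fis.items()},
            "beta": summary.beta,
            "mean_he": summary.mean_he,
            "ne_moment": summary.ne_moment,
            "diversity_loss_F": summary.diversity_loss_f,
            "lnrh_outliers": int(len(outliers)),
            "expected_false_positives": popstats.expected_false_positives(
                int(np.isfinite(flat["lnrh_z"]).sum()), 0.01
            ),
            "regions_fst": scan_results["fst"].regions.to_dict("records"),
            "regions_lnrh": scan_results["lnrh"].regions.to_dict("records"),
            "ld_decay": decay,
            "markers_needed": {
                label: popstats.markers_needed(2500.0, d["half_decay_cm"])
                for label, d in decay.items()
                if "half_decay_cm" in d
            },
        }
        report_json = outdir / "summary.json"
        report_json.write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float) + "\n",
            encoding="utf-8",
        )
        manifest.add_output(report_json)
    manifest.add_stage("report", t.seconds, len(report))

    manifest.write(outdir / "manifest.json")
    return manifest
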