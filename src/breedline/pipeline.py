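"""Config-driven end-to-end run: (simulate | load) -> QC -> sharing -> PCA ->
F_ST -> ranking/enrichment -> haplotypes -> diversity -> calibration.

A single global seed fans out to per-stage child seeds by fixed offsets, so
identical config + seed gives byte-identical numeric outputs while stages stay
decoupled.  Machine outputs go only to files under the output directory; a
manifest records the seed, input hashes, per-stage outputs and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from breedline import calibration as calib_mod
from breedline import diversity as div_mod
from breedline import fst as fst_mod
from breedline.genotypes import (
    DataError,
    GenotypeMatrix,
    PopulationLabels,
    apply_qc,
    read_ped_map,
    read_population_labels,
    write_ped_map,
    write_population_labels,
)
from breedline.haplotypes import EmSettings, em_haplotype_frequencies, poll_style_report
from breedline.pca import pcoa_from_sharing, separation_score, subset_and_embed, write_coordinates_tsv
from breedline.sharing import cluster_order, sharing_matrix, write_sharing_tsv
from breedline.simulate import (
    DriftConfig,
    HaplotypeBlockConfig,
    inject_haplotype_block,
    simulate_balding_nichols,
    vector_from_named,
)

log = logging.getLogger("breedline")

_KNOWN_KEYS = {
    "simulation",
    "input",
    "qc",
    "pca",
    "fst",
    "haplotypes",
    "diversity",
    "calibration",
    "seed",
    "outdir",
    "make_plots",
}


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    simulation: dict | None = None
    input: dict | None = None
    qc: dict = field(default_factory=dict)
    pca: dict = field(default_factory=lambda: {"k": 4, "dims": 2, "subsets": []})
    fst: dict = field(default_factory=lambda: {"n_boot": 200, "top_fractions": [0.01, 0.05]})
    haplotypes: dict | None = None
    diversity: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    make_plots: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.simulation is None) == (self.input is None):
            raise DataError("config must set exactly one of 'simulation' / 'input'")
        for q in self.fst.get("top_fractions", []):
            if not 0 < q < 1:
                raise DataError(f"top fraction {q} not in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw or "outdir" not in raw:
            raise DataError("config requires 'seed' and 'outdir'")
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _stage_inputs(cfg: RunConfig, outdir: Path) -> tuple[GenotypeMatrix, PopulationLabels, list[Path]]:
    if cfg.simulation is not None:
        sim = dict(cfg.simulation)
        block_spec = sim.pop("haplotype_block", None)
        drift = DriftConfig(seed=cfg.seed + 1, **sim)
        g, snp_map, labels, truth = simulate_balding_nichols(drift)
        if block_spec:
            window = list(block_spec["window_snps"])
            idx = snp_map.index_of(window)
            alleles = [
                (snp_map.table["allele_a"].iloc[i], snp_map.table["allele_b"].iloc[i])
                for i in idx
            ]
            freqs = {}
            for pop, spec in block_spec["frequencies"].items():
                if "binary" in spec:
                    # haplotypes keyed by binary strings over (allele_a=0, allele_b=1)
                    m = len(window)
                    vec = np.zeros(2**m)
                    for hap, f in spec["binary"].items():
                        vec[int(hap, 2)] = f
                    rest = vec == 0
                    if rest.any():
                        vec[rest] = spec.get("other", 0.0) / rest.sum()
                    freqs[pop] = vec
                else:
                    freqs[pop] = vector_from_named(
                        dict(spec.get("named", {})), alleles, other=spec.get("other", 0.0)
                    )
            block = HaplotypeBlockConfig(window_snps=window, frequencies=freqs)
            g, truth = inject_haplotype_block(g, truth, labels, block, seed=cfg.seed + 2)
        ped, mp = write_ped_map(g, snp_map, outdir / "simulated")
        lab_path = write_population_labels(labels, outdir / "simulated.labels.tsv")
        truth_path = outdir / "simulated.truth.tsv"
        pd.DataFrame(
            {"snp_id": snp_map.snp_ids, "ancestral_freq": truth.ancestral_freq}
            | {f"freq_{n}": truth.pop_freq[j] for j, n in enumerate(truth.pop_names)}
        ).to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
        return g, labels, [ped, mp, lab_path, truth_path]
    paths = cfg.input
    g, _ = read_ped_map(paths["ped"], paths["map"])
    labels = read_population_labels(paths["labels"])
    labels.validate_against(g)
    return g, labels, [Path(paths["ped"]), Path(paths["map"]), Path(paths["labels"])]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "inputs": {}}
    t_total = time.perf_counter()

    def record(stage: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

    def run_stage(stage, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, outputs, t0)

    # -- inputs ------------------------------------------------------------
    t0 = time.perf_counter()
    g, labels, input_paths = _stage_inputs(cfg, outdir)
    manifest["inputs"] = {str(p): _hash_file(p) for p in input_paths}
    record("input", input_paths, t0)

    # -- qc ----------------------------------------------------------------
    state: dict = {}

    def stage_qc():
        g2, report = apply_qc(
            g,
            snp_call_rate_min=cfg.qc.get("snp_call_rate_min", 0.0),
            sample_call_rate_min=cfg.qc.get("sample_call_rate_min", 0.0),
            maf_min=cfg.qc.get("maf_min", 0.0),
        )
        state["g"] = g2
        path = outdir / "qc_report.json"
        path.write_text(json.dumps(report.__dict__, indent=2))
        return [path]

    run_stage("qc", stage_qc)
    g_qc: GenotypeMatrix = state["g"]

    def stage_sharing():
        s = sharing_matrix(g_qc)
        order = cluster_order(s)
        state["sharing"] = s
        p1 = outdir / "sharing.tsv"
        write_sharing_tsv(s, p1)
        p2 = outdir / "cluster_order.tsv"
        pd.DataFrame(
            {"position": range(len(order.order)), "sample": [s.samples[i] for i in order.order]}
        ).to_csv(p2, sep="\t", index=False)
        out = [p1, p2]
        if cfg.make_plots:
            from breedline.plots import sharing_heatmap

            out.append(sharing_heatmap(s, order, outdir / "sharing_heatmap.png"))
        return out

    run_stage("sharing", stage_sharing)

    def stage_pca():
        k = cfg.pca.get("k", 4)
        res = pcoa_from_sharing(state["sharing"], k)
        state["pca"] = res
        p1 = outdir / "pca_coords.tsv"
        write_coordinates_tsv(res, p1)
        rows = [
            {
                "subset": "full",
                "separation_score": separation_score(res, labels, cfg.pca.get("dims", 2)),
            }
        ]
        for i, spec in enumerate(cfg.pca.get("subsets", [])):
            if isinstance(spec, str) and spec.startswith("random:"):
                frac = float(spec.split(":", 1)[1])
                sub = subset_and_embed(g_qc, frac, k, seed=cfg.seed + 3 + i)
            elif isinstance(spec, str) and spec.startswith("top-fst:"):
                frac = float(spec.split(":", 1)[1])
                pair = tuple(state["fst_pairs"][0]) if "fst_pairs" in state else None
                comp = fst_mod.fst_components(g_qc, labels, pair or _first_pair(labels))
                top = fst_mod.rank_top_fraction(comp.per_snp_fst, comp.snp_ids, frac)
                sub = subset_and_embed(g_qc, top, k)
            else:
                raise DataError(f"unknown PCA subset spec {spec!r}")
            rows.append(
                {
                    "subset": spec,
                    "separation_score": separation_score(sub, labels, cfg.pca.get("dims", 2)),
                }
            )
        p2 = outdir / "separation_scores.tsv"
        pd.DataFrame(rows).to_csv(p2, sep="\t", index=False, float_format="%.4f")
        out = [p1, p2]
        if cfg.make_plots:
            from breedline.plots import pca_scatter

            out.append(pca_scatter(res, labels.assignments, outdir / "pca_scatter.png"))
        return out

    def _first_pair(lab: PopulationLabels) -> tuple[str, str]:
        pops = lab.populations()
        return (pops[0], pops[1])

    run_stage("pca", stage_pca)

    def stage_fst():
        results = fst_mod.pairwise_fst_matrix(
            g_qc, labels, n_boot=cfg.fst.get("n_boot", 200), seed=cfg.seed + 4
        )
        state["fst_results"] = results
        state["fst_pairs"] = list(results)
        p1 = outdir / "fst_matrix.tsv"
        fst_mod.format_fst_table(results).to_csv(p1, sep="\t", index_label="population")
        first = next(iter(results.values()))
        p2 = outdir / "fst_per_snp.tsv"
        pd.DataFrame(
            {
                "snp_id": first.snp_ids,
                "chromosome": g_qc.snps.chromosomes,
                "position_bp": g_qc.snps.table["position_bp"],
                "fst": first.per_snp_fst,
            }
        ).to_csv(p2, sep="\t", index=False, float_format="%.6f")
        return [p1, p2]

    run_stage("fst", stage_fst)

    def stage_rank_enrich():
        first = next(iter(state["fst_results"].values()))
        out = []
        for q in cfg.fst.get("top_fractions", [0.01, 0.05]):
            top = fst_mod.rank_top_fraction(first.per_snp_fst, first.snp_ids, q)
            p = outdir / f"top_snps_{q:g}.tsv"
            pd.Series(top, name="snp_id").to_csv(p, sep="\t", index=False)
            enr = fst_mod.chromosome_enrichment(top, g_qc.snps)
            pe = outdir / f"enrichment_{q:g}.tsv"
            enr.to_csv(pe, sep="\t", index=False, float_format="%.6g")
            out += [p, pe]
            if cfg.make_plots:
                from breedline.plots import enrichment_bars

                out.append(enrichment_bars(enr, outdir / f"enrichment_{q:g}.png"))
        return out

    run_stage("rank_enrich", stage_rank_enrich)

    def stage_haplotypes():
        if not cfg.haplotypes:
            p = outdir / "haplotypes.tsv"
            p.write_text("# no haplotype window configured\n")
            return [p]
        window = list(cfg.haplotypes["window"])
        named = [tuple(x) for x in cfg.haplotypes.get("named", [])]
        settings = EmSettings(seed=cfg.seed + 5)
        tables = {
            pop: em_haplotype_frequencies(g_qc, window, labels.samples_in(pop), settings)
            for pop in labels.populations()
        }
        report = poll_style_report(tables, named) if named else pd.DataFrame(
            {
                "population": list(tables),
                "n_animals": [t.n_used for t in tables.values()],
            }
        )
        p = outdir / "haplotypes.tsv"
        report.to_csv(p, sep="\t", index=False)
        return [p]

    run_stage("haplotypes", stage_haplotypes)

    def stage_diversity():
        rep = div_mod.diversity_report(g_qc, labels, cfg.diversity.get("g_copies"))
        p = outdir / "diversity.tsv"
        rep.to_csv(p, sep="\t", index=False, float_format="%.4f")
        return [p]

    run_stage("diversity", stage_diversity)

    def stage_calibration():
        fixture = calib_mod.load_fst_fixture()
        table = calib_mod.calibration_table(fixture.fst_percent)
        p1 = outdir / "calibration.tsv"
        table.to_csv(p1, sep="\t", index=False, float_format="%.4f")
        cand_cfg = cfg.calibration
        if cand_cfg.get("candidate_pair"):
            pair = tuple(cand_cfg["candidate_pair"])
            candidate = state["fst_results"][pair].global_fst * 100
        else:
            candidate = next(iter(state["fst_results"].values())).global_fst * 100
        verdict = calib_mod.breed_verdict(
            candidate,
            table,
            cand_cfg.get("line_category", "Selection lines within breed"),
            cand_cfg.get("breed_category", "Breed pairs of Mediterranean origin"),
        )
        p2 = outdir / "verdict.json"
        p2.write_text(json.dumps(verdict, indent=2))
        return [p1, p2]

    run_stage("calibration", stage_calibration)

    manifest["total_seconds"] = round(time.perf_counter() - t_total, 3)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
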