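"""End-to-end pipeline driver, configuration, and summary report.

`run_pipeline` chains the whole analysis: simulate the calibration series,
summarize the packaged specimen panel (hybrid ratios, heterozygosity
census), enumerate parental-lineage hypotheses, build the bootstrapped NJ
tree over the thirteen ITS haplotypes, and probe the hybrid-ratio vs
altitude relationship. All outputs are plain text (TSV, Newick, FASTA)
and byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__, additivity, genotyping, its_regions, phylogeny
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.10, 0.15, 0.20, 0.30, 0.40, 0.50)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study's defaults.

    calibration_reps = 5 and specimen_reps = 3 mirror the replicate counts
    of the calibration series and of the per-specimen ratio measurements;
    alpha = 0.01 and direct_threshold = 0.15 are the additivity decision
    rule; noise_window (117, 127) is the default I0 window around site 122.
    """

    seed: int = 1
    calibration_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    calibration_reps: int = 5
    specimen_reps: int = 3
    alpha: float = 0.01
    direct_threshold: float = 0.15
    min_secondary: float = additivity.DEFAULT_MIN_SECONDARY
    noise_window: tuple[int, int] = (117, 127)
    bootstrap_replicates: int = 1000
    outdir: str = "results"
    sim_overrides: dict = field(default_factory=dict)

    def sim_params(self) -> sd.SimParams:
        return sd.SimParams(seed=self.seed, **self.sim_overrides)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["calibration_fractions"] = list(self.calibration_fractions)
        data["noise_window"] = list(self.noise_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "calibration_fractions" in data:
            data["calibration_fractions"] = tuple(data["calibration_fractions"])
        if "noise_window" in data:
            data["noise_window"] = tuple(data["noise_window"])
        return cls(**data)


def correlate_geography(panel: pd.DataFrame) -> dict:
    """Pearson/Spearman association of per-specimen mean hybrid ratio with altitude.

    Reported as-is, never thresholded into a claim. Specimens without a
    measurable ratio (no additive peak quantified) are dropped; fewer than
    3 complete pairs, or a constant column, make the correlation not
    computable and are reported as such.
    """
    ratio = panel[["ratio122_mean", "ratio226_mean"]].mean(axis=1, skipna=True)
    df = pd.DataFrame({"ratio": ratio, "altitude": panel["altitude_m"]}).dropna()
    if len(df) < 3:
        return {"computable": False,
                "reason": f"only {len(df)} complete (ratio, altitude) pairs"}
    if df["altitude"].nunique() == 1 or df["ratio"].nunique() == 1:
        return {"computable": False, "reason": "constant column", "n": len(df)}
    pr, pp = stats.pearsonr(df["ratio"], df["altitude"])
    sr, sp = stats.spearmanr(df["ratio"], df["altitude"])
    return {"computable": True, "n": int(len(df)),
            "pearson_r": float(pr), "pearson_p": float(pp),
            "spearman_rho": float(sr), "spearman_p": float(sp)}


def round_trip_type_assignment(panel: pd.DataFrame | None = None,
                               reference: str | None = None,
                               params: sd.SimParams | None = None,
                               n_reps: int = 3,
                               min_secondary: float | None = None,
                               ) -> pd.DataFrame:
    """Re-derive every specimen's ITS type through the full trace pipeline.

    For each specimen, ``n_reps`` replicate forward/reverse trace pairs are
    rendered with the specimen's published hybrid ratios as the
    minor-template fractions (heterozygous sites without a published ratio
    use the renderer's default fraction); candidate sites are screened on
    both strands, confirmed by the replicate S-vs-N analysis, genotyped,
    and matched back to a named type. Returns the panel with a
    ``called_type`` column.
    """
    panel = panel.copy() if panel is not None else sd.build_specimen_panel()
    params = params if params is not None else sd.SimParams()
    reference = reference if reference is not None else sd.make_reference(
        seed=params.seed)
    rng = params.rng()
    called = []
    for row in panel.itertuples(index=False):
        tdef = genotyping.TYPE_DEFS[row.its_type]
        fracs = {}
        for pos, col in ((122, "ratio122_mean"), (226, "ratio226_mean")):
            v = getattr(row, col)
            if not np.isnan(v) and tdef.genotypes[pos].heterozygous:
                fracs[pos] = v / 100.0
        pairs = [sd.render_type_traces(row.its_type, reference,
                                       site_fractions=fracs,
                                       params=params, rng=rng)
                 for _ in range(n_reps)]
        genos, _ = genotyping.genotypes_from_trace_replicates(
            pairs, min_secondary=min_secondary
            if min_secondary is not None else additivity.DEFAULT_MIN_SECONDARY)
        canonical = {p: g for p, g in genos.items()
                     if p in genotyping.VARIABLE_SITES}
        called.append(genotyping.assign_type(row.species, canonical))
    panel["called_type"] = called
    return panel


def _lineage_frame() -> pd.DataFrame:
    rows = []
    for label, tdef in genotyping.CULTIVAR_TYPES.items():
        crosses = genotyping.infer_single_cross(tdef)
        cross_txt = "; ".join(" x ".join(sorted(p)) for p in sorted(crosses, key=sorted))
        two_step = genotyping.enumerate_two_step(tdef)
        chain_txt = "; ".join(
            f"{' x '.join(sorted(first))} -> {inter}, then {inter} x {second}"
            for first, inter, second in two_step)
        note = ""
        if not crosses and tdef.heterozygous:
            hypos = genotyping.hypothetical_missing_parent(tdef)
            note = "; ".join(
                "HYPOTHETICAL unsampled parent "
                + "".join(geno[p] for p in genotyping.VARIABLE_SITES)
                + f" x {line}" for geno, line in hypos)
        rows.append({"its_type": label,
                     "single_crosses": cross_txt,
                     "two_step_chains": chain_txt,
                     "note": note})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute simulate -> calibrate -> type -> lineage -> tree -> report.

    Returns a mapping of artifact names to output paths. Any stage error
    propagates with a stage-named message.
    """
    out = Path(config.outdir)
    if not out.exists():
        out.mkdir(parents=True)
        logger.info("created output directory %s", out)
    paths: dict[str, Path] = {}
    params = config.sim_params()

    current = "setup"

    def stage(name):
        nonlocal current
        current = name
        logger.info("stage: %s", name)

    try:
        stage("reference")
        reference = sd.make_reference(seed=config.seed)
        seqs = {label: sd.render_type_sequence(label, reference)
                for label in genotyping.TYPE_DEFS}
        paths["sequences"] = out / "type_sequences.fasta"
        sd.write_fasta(seqs, paths["sequences"])

        stage("regions")
        regions = its_regions.extract_regions(reference)
        reg_rows = [{"region": r.name, "start": r.start, "end": r.end,
                     "length": len(r), "gc_percent": its_regions.gc_content(r.sequence)}
                    for r in (regions.its1, regions.s58, regions.its2)]
        paths["regions"] = out / "regions.tsv"
        pd.DataFrame(reg_rows).to_csv(paths["regions"], sep="\t", index=False)

        stage("calibrate")
        rows = additivity.calibration_table(
            config.calibration_fractions, n=config.calibration_reps,
            params=params, alpha=config.alpha)
        paths["calibration"] = out / "calibration.tsv"
        additivity.calibration_frame(rows).to_csv(
            paths["calibration"], sep="\t", index=False)
        limit = additivity.smallest_significant_fraction(rows)

        stage("panel")
        panel = sd.build_specimen_panel()
        paths["specimens"] = out / "specimens.tsv"
        panel.to_csv(paths["specimens"], sep="\t", index=False)
        agg = additivity.aggregate_ratios_by_type(panel)
        paths["ratios"] = out / "ratios_by_type.tsv"
        agg.round(2).to_csv(paths["ratios"], sep="\t")
        census = genotyping.census_heterozygosity(panel)

        stage("lineage")
        lineage = _lineage_frame()
        paths["lineage"] = out / "lineage.tsv"
        lineage.to_csv(paths["lineage"], sep="\t", index=False)

        stage("tree")
        tree, support = phylogeny.bootstrap_support(
            seqs, replicates=config.bootstrap_replicates, seed=config.seed)
        paths["tree"] = out / "tree.nwk"
        phylogeny.write_newick(tree, paths["tree"])
        paths["distances"] = out / "distances.phylip"
        phylogeny.write_phylip(phylogeny.distance_matrix(seqs),
                               paths["distances"])

        stage("geography")
        geo = correlate_geography(panel)

        stage("report")
        paths["report"] = out / "report.txt"
        with open(paths["report"], "w") as fh:
            fh.write(f"codonits {__version__} pipeline report (seed={config.seed})\n\n")
            fh.write(f"ITS regions: ITS1={len(regions.its1)} nt, "
                     f"5.8S={len(regions.s58)} nt, ITS2={len(regions.its2)} nt, "
                     f"total={len(regions.its)} nt\n")
            if limit is None:
                fh.write("calibration: no fraction reached significance\n")
            else:
                fh.write(f"calibration detection limit: {limit * 100:.0f}% "
                         f"minor template (alpha={config.alpha})\n")
            fh.write(f"census: {census['heterozygous']}/{census['total']} "
                     "specimens heterozygous "
                     f"({census['pure']} pure line)\n")
            fh.write("mean hybrid ratio by type (percent):\n")
            fh.write(agg.round(2).to_string() + "\n")
            fh.write(
                "note: the in-print multi-specimen averages for P1, PM1, P4, "
                "P5 and PM2 do not equal the arithmetic means of the "
                "per-specimen table and are not reproduced here; the "
                "single-specimen types (P2, P3, PM3) agree exactly.\n")
            disc = ", ".join(sd.TYPE_DISCREPANT_VOUCHERS)
            fh.write(f"note: type assignments for {disc} differ between the "
                     "two source tables; the hybrid-ratio table is used.\n")
            if geo.get("computable"):
                fh.write(
                    "hybrid ratio vs altitude: "
                    f"Pearson r={geo['pearson_r']:.3f} (p={geo['pearson_p']:.3f}), "
                    f"Spearman rho={geo['spearman_rho']:.3f} "
                    f"(p={geo['spearman_p']:.3f}), n={geo['n']}\n")
            else:
                fh.write(f"hybrid ratio vs altitude: not computable "
                         f"({geo.get('reason')})\n")
        paths["config"] = out / "config.yaml"
        config.to_yaml(paths["config"])
        paths["log"] = out / "run.log"
        with open(paths["log"], "w") as fh:
            fh.write(f"codonits version: {__version__}\n")
            fh.write(f"seed: {config.seed}\n")
            fh.write(f"numpy: {np.__version__}\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc
    return paths
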