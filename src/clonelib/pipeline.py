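"""Pipeline orchestration: simulate -> extract/GC -> cluster -> diversity
-> qPCR -> thermal typing -> composition, with TSV outputs and a JSON
run manifest.

Each stage writes its table to ``<name>.tsv.partial`` and renames it on
success, so an interrupted run leaves identifiable partial outputs. The
manifest records the package version, seed, and a hash of the canonical
config, making a rerun with the same config+seed byte-identifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_otus, pairwise_p_distance
from .composition import aggregate
from .diversity import CloneLibrary, diversity_table
from .growth_temp import (
    DEFAULT_LIFESTYLE_THRESHOLDS,
    community_thermal_profile,
    fit_temp_model,
    load_calibration,
    predict_growth_temp,
)
from .qpcr import (
    GenomeCopyModel,
    QpcrMeasurement,
    cell_table,
    cells_from_copies,
    domain_fraction,
    guild_fraction,
)
from .sequences import DEFAULT_PRIMERS, Primer, extract_region, gc_percent, read_fasta, write_fasta
from .synthetic import (
    SyntheticCommunitySpec,
    SyntheticQpcrSpec,
    panel_to_measurements,
    simulate_library,
    simulate_qpcr,
)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("clonelib")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, record_id: str | None = None):
        at = f" (record {record_id})" if record_id else ""
        super().__init__(f"stage {stage!r} failed{at}: {cause}")
        self.stage = stage
        self.record_id = record_id
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Validated run configuration; see `RunConfig.from_yaml`."""

    out_dir: str = "clonelib_out"
    seed: int = 0
    input_fasta: str | None = None  # None -> simulate a library
    simulate: dict = field(default_factory=dict)
    fwd_primer: Primer = field(default_factory=lambda: DEFAULT_PRIMERS["109F"])
    rev_primer: Primer = field(default_factory=lambda: DEFAULT_PRIMERS["915R"])
    target_len: int = 800
    max_mismatch: int = 1
    threshold: float = 0.03
    linkage: str = "average"
    qpcr_table: str | None = None  # TSV: year, target, copies_per_gww, sd
    simulate_qpcr: bool = True
    copies_per_genome: dict = field(default_factory=dict)
    calibration: str | None = None  # None -> packaged table
    lifestyle_thresholds: tuple = DEFAULT_LIFESTYLE_THRESHOLDS
    assignments: str | None = None  # TSV: clone_id, year, domain, taxon

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.target_len < 1 or self.max_mismatch < 0:
            raise ValueError("invalid region settings")
        for name in ("input_fasta", "qpcr_table", "calibration", "assignments"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} not found")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        primers = kw.pop("primers", {})
        if "forward" in primers:
            kw["fwd_primer"] = Primer(orientation="forward", **primers["forward"])
        if "reverse" in primers:
            kw["rev_primer"] = Primer(orientation="reverse", **primers["reverse"])
        region = kw.pop("region", {})
        kw.setdefault("target_len", region.get("target_len", 800))
        kw.setdefault("max_mismatch", region.get("max_mismatch", 1))
        if "lifestyle_thresholds" in kw:
            kw["lifestyle_thresholds"] = tuple(kw["lifestyle_thresholds"])
        unknown = set(kw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d["fwd_primer"] = dataclasses.asdict(self.fwd_primer)
        d["rev_primer"] = dataclasses.asdict(self.rev_primer)
        d["lifestyle_thresholds"] = list(self.lifestyle_thresholds)
        return d


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    partial = path.with_suffix(path.suffix + ".partial")
    df.to_csv(partial, sep="\t", index=False)
    os.replace(partial, path)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def done(name: str, df: pd.DataFrame) -> None:
        outputs[name] = str(_write_tsv(df, out / f"{name}.tsv"))
        log.info("stage %s: wrote %s (%d rows)", name, outputs[name], len(df))

    # --- sequences: simulate or load -------------------------------------
    try:
        if config.input_fasta is None:
            spec = SyntheticCommunitySpec(seed=config.seed, **config.simulate)
            records, truth = simulate_library(spec)
            fasta = out / "library.fasta"
            write_fasta(records, fasta)
            outputs["library_fasta"] = str(fasta)
            done("truth", truth)
        else:
            records = read_fasta(config.input_fasta)
            outputs["library_fasta"] = str(config.input_fasta)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("simulate/load", exc) from exc

    # --- region extraction + GC ------------------------------------------
    gc_rows = []
    for rec in records:
        try:
            region = extract_region(
                rec, config.fwd_primer, config.rev_primer,
                max_mismatch=config.max_mismatch, target_len=config.target_len,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("region-gc", exc, rec.id) from exc
        gc_rows.append({
            "clone_id": rec.id,
            "region_start": region.interval.start,
            "region_end": region.interval.end,
            "region_len": len(region.sequence),
            "is_short": region.is_short,
            "p_gc": gc_percent(region.sequence),
        })
    gc_df = pd.DataFrame(gc_rows)
    done("region_gc", gc_df)

    # --- OTU clustering ----------------------------------------------------
    try:
        dm = pairwise_p_distance(records)
        assignment = cluster_otus(dm, config.threshold, config.linkage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("cluster", exc) from exc
    otu_of = assignment.otu_of()
    done("otu_assignments", pd.DataFrame(
        [{"sequence_id": sid, "otu_id": otu} for sid, otu in sorted(otu_of.items())]
    ))
    otu_table = pd.DataFrame({
        "otu_id": sorted(assignment.clusters, key=lambda k: int(k.split("_")[1])),
    })
    otu_table["abundance"] = assignment.abundances
    done("otu_table", otu_table)

    # --- diversity ---------------------------------------------------------
    try:
        lib = CloneLibrary(tuple(otu_table["abundance"]), sample_id="pipeline",
                           marker="16S-archaea")
        done("diversity", diversity_table([lib]))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("diversity", exc) from exc

    # --- qPCR --------------------------------------------------------------
    try:
        measurements: list[QpcrMeasurement] = []
        if config.qpcr_table is not None:
            qdf = pd.read_csv(config.qpcr_table, sep="\t")
            measurements = [
                QpcrMeasurement(
                    target=r["target"], copies_per_gww=float(r["copies_per_gww"]),
                    sd=float(r.get("sd", 0.0)), year=int(r.get("year", 0)),
                )
                for r in qdf.to_dict("records")
            ]
        elif config.simulate_qpcr:
            panel = simulate_qpcr(SyntheticQpcrSpec(seed=config.seed))
            done("qpcr_panel", panel)
            measurements = panel_to_measurements(panel)
        if measurements:
            model = GenomeCopyModel(
                {**GenomeCopyModel().copies_per_genome, **config.copies_per_genome}
            )
            table = cell_table(measurements, model)
            by_target = {
                (m.year, m.target): cells_from_copies(m, model) for m in measurements
            }
            frac_rows = []
            for year in sorted({m.year for m in measurements}):
                arch = by_target.get((year, "16S-archaea"))
                bact = by_target.get((year, "16S-bacteria"))
                rec = {"year": year}
                if arch and bact:
                    rec["archaeal_pct"] = domain_fraction(arch, bact)
                mcra = next((m for m in measurements
                             if m.year == year and m.target == "mcrA"), None)
                dsrb = next((m for m in measurements
                             if m.year == year and m.target == "dsrB"), None)
                if mcra and arch:
                    rec["methanogen_pct_of_archaea"] = guild_fraction(mcra, arch)
                if dsrb and bact:
                    rec["srb_pct_of_bacteria"] = guild_fraction(dsrb, bact)
                frac_rows.append(rec)
            done("cells", table)
            done("fractions", pd.DataFrame(frac_rows))
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("qpcr", exc) from exc

    # --- thermal typing ----------------------------------------------------
    try:
        calib = load_calibration(config.calibration)
        model = fit_temp_model(calib)
        thermal_rows = []
        for row in gc_df.to_dict("records"):
            pred = predict_growth_temp(
                row["p_gc"], model, config.lifestyle_thresholds
            )
            thermal_rows.append({
                "clone_id": row["clone_id"], "otu_id": otu_of[row["clone_id"]],
                "p_gc": pred.p_gc, "t_min": pred.t_min, "t_opt": pred.t_opt,
                "t_max": pred.t_max, "lifestyle": pred.lifestyle,
            })
        thermal = pd.DataFrame(thermal_rows)
        done("thermal", thermal)
        summary = (
            thermal.groupby("otu_id")
            .agg(n_clones=("clone_id", "size"), mean_p_gc=("p_gc", "mean"))
            .reset_index()
        )
        summary["t_opt_weighted"] = [
            community_thermal_profile(
                thermal.loc[thermal["otu_id"] == otu, "t_opt"],
                [1] * int(n),
            )
            for otu, n in zip(summary["otu_id"], summary["n_clones"])
        ]
        done("thermal_summary", summary)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("thermotype", exc) from exc

    # --- composition (only when assignments are supplied) -------------------
    if config.assignments is not None:
        try:
            adf = pd.read_csv(config.assignments, sep="\t")
            done("composition", aggregate(adf, pool=False))
            done("composition_pooled", aggregate(adf, pool=True))
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("compose", exc) from exc

    canon = json.dumps(config.canonical(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
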