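"""End-to-end run: simulate -> haplotype -> chimera-split -> map -> anchor -> build.

One :class:`RunConfig` (YAML-serializable, unknown keys rejected) drives all
stages; every intermediate is written as TSV/FASTA/AGP and a JSON manifest
echoes the effective configuration together with per-stage counts.
Identical (config, seed) pairs reproduce byte-identical data files.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import MarkerTable
from .haplo import (
    DEFAULT_BLOCK_SIZE,
    DEFAULT_MAJORITY_THRESHOLD,
    DEFAULT_MIN_MARKERS,
    DEFAULT_MIN_SUPPORT,
    DEFAULT_TAU,
    apply_chimera_splits,
    chimera_report_frame,
    compute_switch_profile,
    consensus_matrix,
    detect_chimeras,
    switch_profile_frame,
)
from .linkmap import (
    DEFAULT_LOD_MIN,
    DEFAULT_MIN_INFORMATIVE,
    DEFAULT_MIN_LEN_BP,
    DEFAULT_R_MAX,
    build_binmap,
)
from .anchor import (
    DEFAULT_MISASSEMBLY_TOLERANCE,
    DEFAULT_REFINE_WINDOW,
    DEFAULT_SPACER_BP,
    build_pseudomolecules,
    find_telomere_arrays,
    flag_misassembly,
    initial_order,
    place_superscaffold,
    placement_frame,
    refine_order,
)
from .genotypes import majority_vector
from .seqio import write_agp, write_fasta
from .simpop import (
    PRESETS,
    SimConfig,
    SuperscaffoldLayout,
    layouts_to_frame,
    scaffold_sequences,
    simulate,
    write_truth,
)

logger = logging.getLogger("mapanchor")


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass
class HaploParams:
    min_markers: int = DEFAULT_MIN_MARKERS
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD
    block_size: int = DEFAULT_BLOCK_SIZE
    tau: float = DEFAULT_TAU
    min_support: int = DEFAULT_MIN_SUPPORT


@dataclass
class LinkmapParams:
    lod_min: float = DEFAULT_LOD_MIN
    r_max: float = DEFAULT_R_MAX
    min_len_bp: int = DEFAULT_MIN_LEN_BP
    min_informative: int = DEFAULT_MIN_INFORMATIVE
    max_mismatch: int = 0


@dataclass
class AnchorParams:
    spacer_bp: int = DEFAULT_SPACER_BP
    misassembly_tolerance: int = DEFAULT_MISASSEMBLY_TOLERANCE
    refine_window: int = DEFAULT_REFINE_WINDOW
    telomere_motif: str = "TTTAGGG"
    telomere_min_copies: int = 10
    telomere_window_bp: int = 10_000
    build_fasta: bool = True


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    haplo: HaploParams = field(default_factory=HaploParams)
    linkmap: LinkmapParams = field(default_factory=LinkmapParams)
    anchor: AnchorParams = field(default_factory=AnchorParams)
    superscaffold_misjoin_fraction: float = 0.0
    seed: int = 0
    outdir: str = "mapanchor_run"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        sections = {
            "sim": SimConfig,
            "haplo": HaploParams,
            "linkmap": LinkmapParams,
            "anchor": AnchorParams,
        }
        kwargs: dict[str, Any] = {}
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if key in sections:
                klass = sections[key]
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                allowed = {f.name for f in dataclasses.fields(klass)}
                bad = set(value) - allowed
                if bad:
                    raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
                coerced = dict(value)
                for tup in ("chrom_genetic_lengths", "chrom_physical_lengths"):
                    if tup in coerced:
                        coerced[tup] = tuple(coerced[tup])
                try:
                    kwargs[key] = klass(**coerced)
                except ValueError as exc:
                    raise ConfigError(str(exc)) from exc
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_genotype_table(path: str | Path) -> MarkerTable:
    """Read and validate a genotype TSV (see :mod:`mapanchor.genotypes`)."""
    return MarkerTable.from_tsv(path)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in order; returns the run manifest (also written).

    Stages: simulate the study population and assembly, write the genotype
    table and truth; consensus haplotypes and chimera detection; split
    called chimeras; linkage-group clustering, binning and ordering;
    superscaffold placement, misassembly flagging, orientation and
    double-recombinant order refinement; pseudomolecule FASTA/AGP and
    telomere search (sequence stages only when ``anchor.build_fasta``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict[str, Any] = {
        "tool": "mapanchor",
        "version": __version__,
        "config": config.to_dict(),
        "started": datetime.datetime.now().isoformat(timespec="seconds"),
        "stages": {},
    }
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        rng = np.random.default_rng(config.seed)
        sim = simulate(
            sim_cfg,
            rng,
            superscaffold_misjoin_fraction=config.superscaffold_misjoin_fraction,
        )
        sim.table.to_tsv(outdir / "genotypes.tsv")
        write_truth(sim.truth, outdir)
        lengths = sim.truth.scaffold_lengths()
        seqs = None
        if config.anchor.build_fasta:
            seqs = scaffold_sequences(sim.truth, rng)
            write_fasta(outdir / "scaffolds.fasta", seqs)
        manifest["stages"][stage] = {
            "scaffolds": len(lengths),
            "markers": sim.table.n_markers,
            "rils": sim.table.n_rils,
            "planted_chimeras": len(sim.truth.chimeras),
            "superscaffolds": len(sim.layouts),
        }
        logger.info("simulate: %s", manifest["stages"][stage])

        stage = "haplotype+chimera"
        hp = config.haplo
        reports = detect_chimeras(
            sim.table, hp.block_size, hp.majority_threshold, hp.tau, hp.min_support
        )
        profiles = [
            compute_switch_profile(sim.table, sid, hp.block_size, hp.majority_threshold)
            for sid in sim.table.scaffold_ids()
        ]
        switch_profile_frame(profiles).to_csv(
            outdir / "switch_profiles.tsv", sep="\t", index=False
        )
        chimera_report_frame(reports).to_csv(
            outdir / "chimera_report.tsv", sep="\t", index=False
        )
        n_chimeric = sum(1 for r in reports.values() if r.verdict == "chimeric")
        table, split_map, lengths, seqs = apply_chimera_splits(
            sim.table, reports, lengths, seqs
        )
        split_map.to_csv(outdir / "split_map.tsv", sep="\t", index=False)
        layouts = _split_layouts(sim.layouts, split_map)
        layouts_to_frame(layouts).to_csv(outdir / "layouts.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "chimeric_scaffolds": n_chimeric,
            "splits": int((split_map.groupby("old_id").size() > 1).sum()),
            "scaffolds_after_split": len(lengths),
        }
        logger.info("chimera: %s", manifest["stages"][stage])

        stage = "map"
        hap = consensus_matrix(table, hp.min_markers, hp.majority_threshold)
        hap.to_tsv(outdir / "haplotypes.tsv")
        lm = config.linkmap
        bin_map = build_binmap(
            hap,
            lengths,
            lm.lod_min,
            lm.r_max,
            lm.min_len_bp,
            lm.min_informative,
            lm.max_mismatch,
        )
        bin_map.to_tsv(outdir / "map.tsv")
        manifest["stages"][stage] = {
            "linkage_groups": len(bin_map.lgs),
            "bins": int(sum(len(b) for b in bin_map.lgs.values())),
            "placed_scaffolds": len(bin_map.scaffold_to),
            "unplaced_scaffolds": len(bin_map.unplaced),
        }
        logger.info("map: %s", manifest["stages"][stage])

        stage = "anchor"
        placements = {}
        mis_rows = []
        for layout in layouts:
            p = place_superscaffold(layout, bin_map)
            mis, split_at = flag_misassembly(
                layout, bin_map, config.anchor.misassembly_tolerance
            )
            if mis:
                p.status = "misassembled"
                mis_rows.append((layout.superscaffold_id, split_at))
            placements[layout.superscaffold_id] = p
        layout_by_id = {l.superscaffold_id: l for l in layouts}
        ss_vectors = {
            ss: _superscaffold_vector(layout_by_id[ss], hap)
            for ss in placements
        }
        lg_orders: dict[int, list[str]] = {}
        for lg in sorted(bin_map.lgs):
            members = [
                p for p in placements.values() if p.lg == lg and p.status == "placed"
            ]
            order = initial_order(members)
            lg_orders[lg] = refine_order(order, ss_vectors, config.anchor.refine_window)
        placement_frame(placements).to_csv(
            outdir / "placements.tsv", sep="\t", index=False
        )
        pd.DataFrame(mis_rows, columns=["superscaffold_id", "split_component"]).to_csv(
            outdir / "misassemblies.tsv", sep="\t", index=False
        )
        n_status = pd.Series(
            [p.status for p in placements.values()]
        ).value_counts().to_dict()
        manifest["stages"][stage] = {
            "superscaffolds": len(placements),
            "placed": int(n_status.get("placed", 0)),
            "unplaced": int(n_status.get("unplaced", 0)),
            "misassembled": int(n_status.get("misassembled", 0)),
            "oriented": int(
                sum(
                    1
                    for p in placements.values()
                    if p.status == "placed" and p.orientation != "unoriented"
                )
            ),
        }
        logger.info("anchor: %s", manifest["stages"][stage])

        stage = "build"
        if config.anchor.build_fasta and seqs is not None:
            fasta, agp = build_pseudomolecules(
                lg_orders, placements, layout_by_id, seqs, config.anchor.spacer_bp
            )
            write_fasta(outdir / "pseudomolecules.fasta", fasta)
            write_agp(outdir / "pseudomolecules.agp", agp)
            telo = find_telomere_arrays(
                fasta,
                config.anchor.telomere_motif,
                config.anchor.telomere_min_copies,
                config.anchor.telomere_window_bp,
            )
            pd.DataFrame(
                [(t.object, t.end, t.motif, t.copies) for t in telo],
                columns=["object", "end", "motif", "copies"],
            ).to_csv(outdir / "telomeres.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "pseudomolecules": len(fasta),
                "total_bp": int(sum(len(s) for s in fasta.values())),
                "agp_rows": len(agp),
                "telomere_hits": len(telo),
            }
        else:
            manifest["stages"][stage] = {"skipped": True}
        logger.info("build: %s", manifest["stages"][stage])
    except Exception as exc:  # noqa: BLE001 - rethrown with stage context
        raise StageError(stage, exc) from exc
    manifest["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
    # truth-aware summary (simulation runs always have truth on disk)
    manifest["summary"] = _truth_summary(sim.truth, reports)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    validate_manifest(manifest, outdir)
    return manifest


def _superscaffold_vector(layout: SuperscaffoldLayout, hap) -> np.ndarray:
    vecs = [
        hap.vector(c.scaffold_id)
        for c in layout.components
        if c.scaffold_id in hap
    ]
    if not vecs:
        return np.full(len(hap.ril_ids), 3, dtype=np.int8)
    return majority_vector(np.stack(vecs))


def _split_layouts(
    layouts: list[SuperscaffoldLayout], split_map: pd.DataFrame
) -> list[SuperscaffoldLayout]:
    """Replace split chimeric scaffolds inside superscaffold layouts.

    A '+' component expands to its parts in order; a '-' component to the
    parts in reverse order, each on the '-' strand, so the emitted sequence
    is unchanged apart from the new component boundaries.
    """
    parts_of: dict[str, list[tuple[str, int]]] = {}
    for old_id, grp in split_map.groupby("old_id"):
        grp = grp.sort_values("start")
        parts_of[old_id] = [
            (row["new_id"], int(row["end"] - row["start"])) for _, row in grp.iterrows()
        ]
    out = []
    for layout in layouts:
        parts: list[tuple[str, int, str]] = []
        for comp in layout.components:
            pieces = parts_of.get(comp.scaffold_id, [(comp.scaffold_id, comp.end - comp.start)])
            if comp.strand == "-":
                pieces = list(reversed(pieces))
            parts.extend((pid, plen, comp.strand) for pid, plen in pieces)
        gap = next((c.gap_after for c in layout.components if c.gap_after), 100)
        out.append(
            SuperscaffoldLayout.from_parts(layout.superscaffold_id, parts, gap)
        )
    return out


def _truth_summary(truth, reports) -> dict[str, Any]:
    planted = set(truth.chimeras["scaffold_id"])
    called = {s for s, r in reports.items() if r.verdict == "chimeric"}
    clean_tested = {
        s for s, r in reports.items() if r.verdict != "untestable"
    } - planted
    tp = len(called & planted)
    recall = tp / len(planted) if planted else float("nan")
    precision = tp / len(called) if called else float("nan")
    fpr = len(called - planted) / len(clean_tested) if clean_tested else 0.0
    return {
        "chimera_recall": round(recall, 4) if planted else None,
        "chimera_precision": round(precision, 4) if called else None,
        "chimera_false_positive_rate": round(fpr, 4),
    }


def validate_manifest(manifest: dict[str, Any], outdir: str | Path) -> None:
    """Cross-check manifest counts against the stage output files."""
    outdir = Path(outdir)
    table = MarkerTable.from_tsv(outdir / "genotypes.tsv")
    sim_counts = manifest["stages"]["simulate"]
    if table.n_markers != sim_counts["markers"] or table.n_rils != sim_counts["rils"]:
        raise ValueError("manifest/simulate counts disagree with genotypes.tsv")
    map_df = pd.read_csv(outdir / "map.tsv", sep="\t")
    placed = int((map_df["LG"] > 0).sum())
    if placed != manifest["stages"]["map"]["placed_scaffolds"]:
        raise ValueError("manifest/map counts disagree with map.tsv")
    chim = pd.read_csv(outdir / "chimera_report.tsv", sep="\t")
    n_chimeric = chim.loc[chim["verdict"] == "chimeric", "scaffold_id"].nunique()
    if n_chimeric != manifest["stages"]["haplotype+chimera"]["chimeric_scaffolds"]:
        raise ValueError("manifest/chimera counts disagree with chimera_report.tsv")


def write_reports(manifest: dict[str, Any], outdir: str | Path) -> None:
    """Plain-text run summary next to the stage outputs."""
    outdir = Path(outdir)
    lines = [f"mapanchor {manifest['version']} run summary"]
    for stage, counts in manifest["stages"].items():
        lines.append(f"[{stage}]")
        for key, val in counts.items():
            lines.append(f"  {key}: {val}")
    summary = manifest.get("summary") or {}
    if summary:
        lines.append("[truth-based evaluation]")
        for key, val in summary.items():
            lines.append(f"  {key}: {'not-available' if val is None else val}")
    (outdir / "run_summary.txt").write_text("\n".join(lines) + "\n")
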