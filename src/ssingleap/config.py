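"""Run configuration and end-to-end orchestration.

A run is described by a flat YAML mapping (paths, thresholds, seeds, mode
flags). ``run_all`` executes simulate-or-load -> site calling -> metrics ->
hotspots -> enrichment and writes every table plus a manifest with input
checksums, parameters and the package version, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io_formats import (
    load_genome,
    load_intervals,
    load_size_profile,
    write_sites,
)
from .metrics import compute_apl, apf_from_stats
from .sitecall import read_fastq_pairs, run_pipeline
from .hotspots import HotspotCatalog, call_hotspots, shared_hotspots
from .enrich import or_elements, or_repeats

__all__ = ["RunConfig", "load_config", "run_all"]


@dataclass
class RunConfig:
    """Flat configuration; defaults are the published pipeline thresholds."""

    genome: str = ""
    repeats: str = ""
    fastq1: str = ""
    fastq2: str = ""
    elements: str = ""
    expression: str = ""
    size_profile: str = ""
    mode: str = "ap"  # ap or ssb
    enzyme: str = "APE1"
    sample_id: str = "sample"
    tissue: str = ""
    age: float | None = None
    min_depth: int = 2
    mapq: int = 20
    polya_window: int = 20
    polya_threshold: float = 0.40
    n_permutations: int = 100
    seed: int = 0
    outdir: str = "ssingleap_out"

    def validate(self) -> None:
        for key in ("genome", "fastq1", "fastq2"):
            value = getattr(self, key)
            if not value:
                raise ValueError(f"config field {key!r} is required")
            if not Path(value).exists():
                raise FileNotFoundError(f"{key}: no such file {value!r}")
        for key in ("repeats", "elements", "expression", "size_profile"):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise FileNotFoundError(f"{key}: no such file {value!r}")
        if self.mode not in ("ap", "ssb"):
            raise ValueError("mode must be 'ap' or 'ssb'")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline per configuration; returns the output dir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"ssingleap {__version__}"]

    genome = load_genome(config.genome, config.repeats or None)
    log.append(
        f"genome: {len(genome.sequences)} sequences, {genome.total_len} bp, "
        f"{genome.nonrepeat_len} bp nonrepeat"
    )
    reads = read_fastq_pairs(config.fastq1, config.fastq2)
    sites, stats = run_pipeline(
        reads,
        genome,
        mode=config.mode,
        sample_id=config.sample_id,
        tissue=config.tissue,
        age=config.age,
        enzyme=config.enzyme,
    )
    write_sites(sites, outdir / "sites.bed")
    with open(outdir / "stats.tsv", "w") as fh:
        fh.write("stage\tcount\n")
        for stage, count in stats.to_rows():
            fh.write(f"{stage}\t{count}\n")
    log.extend(f"{stage}: {count}" for stage, count in stats.to_rows())

    with open(outdir / "metrics.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        apf = apf_from_stats(stats)
        name = "APF" if config.mode == "ap" else "ASF"
        fh.write(f"{name}\t{'' if apf is None else f'{apf:.6f}'}\n")
        if config.size_profile:
            apl = compute_apl(load_size_profile(config.size_profile))
            fh.write(f"APL\t{'' if apl is None else f'{apl:.6f}'}\n")

    hotspot_set = call_hotspots(sites, config.min_depth)
    catalog = HotspotCatalog({config.sample_id: sites}, min_depth=config.min_depth)
    _, summary = shared_hotspots(catalog)
    with open(outdir / "hotspots.tsv", "w") as fh:
        fh.write("chrom\tpos0\tstrand\tdepth\n")
        for chrom, pos, strand in sorted(hotspot_set):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{sites.sites[(chrom, pos, strand)]}\n")
    log.append(f"hotspots (depth >= {config.min_depth}): {len(hotspot_set)}")

    rows: list[str] = ["mode\tclass\tobserved\texpected\todds_ratio\tn_obs\tn_total\tp"]
    if len(genome.repeat_mask):
        for cls, er in sorted(or_repeats(
            sites, genome.repeat_mask, genome.total_len).items()):
            rows.append(_er_row(er))
    if config.elements:
        elements = load_intervals(config.elements)
        for cls, er in sorted(or_elements(sites, elements, genome).items()):
            rows.append(_er_row(er))
    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("\n".join(rows) + "\n")

    manifest = {
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "inputs": {
            key: _sha256(getattr(config, key))
            for key in ("genome", "repeats", "fastq1", "fastq2",
                        "elements", "expression", "size_profile")
            if getattr(config, key)
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return outdir


def _er_row(er) -> str:
    def fmt(x):
        return "" if x is None else (f"{x:.6g}" if isinstance(x, float) else str(x))

    return "\t".join([
        er.mode, er.feature_class, fmt(er.observed_frac), fmt(er.expected_frac),
        fmt(er.odds_ratio), str(er.n_obs), str(er.n_total), fmt(er.p_two_sided),
    ])
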