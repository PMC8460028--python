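"""Isolate table fixture, cohort summaries, and end-to-end pipeline runs.

The packaged TSV transcribes the published genomic-sequencing results for
the sixteen spontaneous 2DG-resistant diploid isolates (DS series):
candidate point mutations / duplications, aneuploid chromosomes by class,
and the growth phenotype. Summary counts are computed from the table, never
hard-coded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
import importlib.resources

from . import genome as genome_mod
from .depth_io import read_depth
from .ploidy import (
    ChromosomeCall,
    KaryotypeCall,
    classify,
    normalize,
    summarize_isolates,
)
from .synthetic_data import Karyotype, NoiseModel, Segment, simulate_depth

MUTATION_CLASSES = {"missense", "nonsense", "duplication", "none"}
GROWTH_CLASSES = {"normal", "slow growth"}


@dataclass(frozen=True)
class IsolateRecord:
    """One sequenced 2DG-resistant isolate: mutation call plus karyotype."""

    name: str
    candidate_mutation: str  # gene-allele string, or "none"
    mutation_class: str  # missense | nonsense | duplication | none
    monosomies: tuple[int, ...]
    trisomies: tuple[int, ...]
    tetrasomies: tuple[int, ...]
    growth: str  # normal | slow growth

    def __post_init__(self) -> None:
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.growth not in GROWTH_CLASSES:
            raise ValueError(f"unknown growth class {self.growth!r}")
        for chrom in self.monosomies + self.trisomies + self.tetrasomies:
            if not 1 <= chrom <= 16:
                raise ValueError(f"chromosome id {chrom} outside 1..16")

    @property
    def is_aneuploid(self) -> bool:
        return bool(self.monosomies or self.trisomies or self.tetrasomies)


def _parse_chrom_list(cell) -> tuple[int, ...]:
    if pd.isna(cell) or str(cell).strip() == "":
        return ()
    return tuple(int(x) for x in str(cell).split(","))


def load_isolate_table(path=None) -> list[IsolateRecord]:
    """Load the packaged (or a user-supplied) isolate table TSV."""
    if path is None:
        ref = importlib.resources.files("aneuscan.data") / "ds_isolates.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {
        "isolate",
        "candidate_mutation",
        "mutation_class",
        "monosomy",
        "trisomy",
        "tetrasomy",
        "growth",
    }
    if set(df.columns) != expected:
        raise ValueError(f"isolate table has unexpected columns {sorted(df.columns)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            IsolateRecord(
                name=row["isolate"],
                candidate_mutation=row["candidate_mutation"],
                mutation_class=row["mutation_class"],
                monosomies=_parse_chrom_list(row["monosomy"]),
                trisomies=_parse_chrom_list(row["trisomy"]),
                tetrasomies=_parse_chrom_list(row["tetrasomy"]),
                growth=row["growth"],
            )
        )
    return records


@dataclass
class FixtureSummary:
    n_total: int
    n_aneuploid: int
    n_monosomy_chr4: int
    n_extra_chr8: int
    n_reg1_nonsense: int
    n_slow_growth: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def fixture_summary(records: list[IsolateRecord]) -> FixtureSummary:
    """Cohort counts recomputed from the isolate records."""
    if not records:
        raise ValueError("no isolate records")
    return FixtureSummary(
        n_total=len(records),
        n_aneuploid=sum(r.is_aneuploid for r in records),
        n_monosomy_chr4=sum(4 in r.monosomies for r in records),
        n_extra_chr8=sum(8 in r.trisomies or 8 in r.tetrasomies for r in records),
        n_reg1_nonsense=sum(
            r.mutation_class == "nonsense" and r.candidate_mutation.startswith("REG1")
            for r in records
        ),
        n_slow_growth=sum(r.growth == "slow growth" for r in records),
    )


def record_to_karyotype(record: IsolateRecord, baseline_ploidy: int = 2) -> Karyotype:
    """Whole-chromosome karyotype implied by one isolate record (segmental
    duplications are not encoded in the chromosome-class columns)."""
    cn: dict[str, int] = {}
    for chrom in record.monosomies:
        cn[f"chr{chrom}"] = baseline_ploidy - 1
    for chrom in record.trisomies:
        cn[f"chr{chrom}"] = baseline_ploidy + 1
    for chrom in record.tetrasomies:
        cn[f"chr{chrom}"] = baseline_ploidy + 2
    return Karyotype(baseline_ploidy=baseline_ploidy, copy_number=cn)


def records_to_calls(
    records: list[IsolateRecord], baseline_ploidy: int = 2
) -> dict[str, KaryotypeCall]:
    """Exact per-chromosome calls regenerated from the isolate table
    (ratio = c/P, integer copy class), ready for summarize_isolates."""
    calls: dict[str, KaryotypeCall] = {}
    for rec in records:
        kt = record_to_karyotype(rec, baseline_ploidy)
        call = KaryotypeCall(baseline_ploidy=baseline_ploidy)
        for i in range(1, 17):
            chrom = f"chr{i}"
            c = kt.copy_of(chrom)
            call.calls[chrom] = ChromosomeCall(
                chrom=chrom,
                median_depth=float("nan"),
                ratio=c / baseline_ploidy,
                copy_class=c,
                mixture_fraction=None,
                mixture_bounds=None,
            )
        calls[rec.name] = call
    return calls


# -- pipeline orchestration ---------------------------------------------------


def _load_genome(cfg, base: Path):
    spec = cfg.get("genome", "default")
    bin_size = int(cfg.get("bin_size", genome_mod.DEFAULT_BIN_SIZE))
    if spec == "default":
        return genome_mod.default_genome(bin_size=bin_size)
    return genome_mod.GenomeModel.from_yaml(base / spec)


def _karyotype_from_cfg(doc) -> Karyotype:
    segs = [
        Segment(s["chrom"], int(s["start"]), int(s["end"]), int(s["copy_number"]))
        for s in doc.get("segments", []) or []
    ]
    return Karyotype(
        baseline_ploidy=int(doc.get("baseline_ploidy", 2)),
        copy_number={k: int(v) for k, v in (doc.get("copy_number") or {}).items()},
        segments=segs,
    )


def run_pipeline(config, base_dir=None) -> dict:
    """Run configured stages (simulate -> ploidy -> segments) and write a
    JSON + Markdown report.

    ``config`` is a YAML path or a dict with keys: seed, genome, bin_size,
    optional stages ``simulate`` (karyotype, coverage, dispersion, out),
    ``ploidy`` (depth, baseline, tolerance, out) and ``segments`` (depth,
    chrom, baseline, min_bins, out), plus ``report.out``. Identical configs
    and seeds give byte-identical report JSON. Missing stage inputs fail
    fast naming the stage.
    """
    if isinstance(config, (str, Path)):
        base = Path(base_dir) if base_dir else Path(config).parent
        raw = Path(config).read_text()
        cfg = yaml.safe_load(raw)
    else:
        base = Path(base_dir) if base_dir else Path.cwd()
        cfg = dict(config)
        raw = yaml.safe_dump(cfg, sort_keys=True)

    gen = _load_genome(cfg, base)
    seed = int(cfg.get("seed", 0))
    report: dict = {
        "provenance": {
            "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
            "seed": seed,
            "version": version_string(),
        },
        "stages": {},
    }
    stages = cfg.get("stages", {})

    profile = None
    if "simulate" in stages:
        sc = stages["simulate"]
        if "karyotype" not in sc:
            raise ValueError("stage 'simulate': missing 'karyotype'")
        kt = _karyotype_from_cfg(sc["karyotype"])
        noise = NoiseModel(
            mean_coverage=float(sc.get("coverage", 100.0)),
            dispersion=float(sc.get("dispersion", 10.0)),
            seed=seed,
        )
        profile = simulate_depth(gen, kt, noise)
        if "out" in sc:
            profile.write_bedgraph(base / sc["out"], header_comments=[f"seed={seed}"])
        report["stages"]["simulate"] = {
            "n_bins": len(profile),
            "coverage": noise.mean_coverage,
            "dispersion": noise.dispersion,
        }

    def _stage_profile(sc, stage: str):
        nonlocal profile
        if "depth" in sc:
            return read_depth(base / sc["depth"], gen)
        if profile is None:
            raise ValueError(f"stage {stage!r}: no 'depth' input and nothing simulated")
        return profile

    if "ploidy" in stages:
        sc = stages["ploidy"]
        prof = _stage_profile(sc, "ploidy")
        call = classify(
            normalize(prof),
            baseline_ploidy=int(sc.get("baseline", 2)),
            tolerance=float(sc.get("tolerance", 0.1)),
        )
        frame = call.to_frame()
        if "out" in sc:
            frame.to_csv(base / sc["out"], sep="\t")
        report["stages"]["ploidy"] = {
            "aneuploid_chromosomes": call.aneuploid_chromosomes,
            "calls": {
                c: {"ratio": round(cc.ratio, 6), "copy_class": cc.copy_class}
                for c, cc in call.calls.items()
            },
        }

    if "segments" in stages:
        from .cnv_segments import detect_segments

        sc = stages["segments"]
        prof = _stage_profile(sc, "segments")
        if "chrom" not in sc:
            raise ValueError("stage 'segments': missing 'chrom'")
        calls = detect_segments(
            prof,
            sc["chrom"],
            baseline_ploidy=int(sc.get("baseline", 2)),
            min_bins=int(sc.get("min_bins", 10)),
        )
        report["stages"]["segments"] = [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "delta_copies": s.delta_copies,
                "length_kb": s.length_kb,
            }
            for s in calls
        ]

    if "fixture_summary" in stages:
        records = load_isolate_table()
        report["stages"]["fixture_summary"] = fixture_summary(records).as_dict()

    out_cfg = cfg.get("report", {})
    json_text = json.dumps(report, sort_keys=True, indent=2)
    if "out" in out_cfg:
        (base / out_cfg["out"]).write_text(json_text + "\n")
        md = base / (str(out_cfg["out"]).rsplit(".", 1)[0] + ".md")
        md.write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# aneuscan pipeline report", ""]
    prov = report["provenance"]
    lines += [
        f"- config sha256: `{prov['config_sha256']}`",
        f"- seed: {prov['seed']}",
        f"- version: {prov['version']}",
        "",
    ]
    for stage, payload in report["stages"].items():
        lines += [f"## {stage}", "", "```json", json.dumps(payload, sort_keys=True, indent=2), "```", ""]
    return "\n".join(lines)


def version_string() -> str:
    from . import __version__

    return __version__
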