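"""Pipeline runner: wire the stages together from a YAML config.

A RunConfig nests per-stage parameter blocks; unknown keys are rejected before
anything runs, and every default matches the study procedure (100 bp barcode
windows, 1,000-2,000 bp length filter, alpha 0.05, abundance 0.01, detection
frequency 0.2, deviation 0.05), so a bare config reproduces that procedure on
any input table. Each run writes its stage outputs plus a provenance manifest
(config hash, seeds, package version, per-file checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .demux import demux_fastq
from .features import FeatureTable
from .sncm import FilterConfig, run_sncm
from .heritability import PedigreeTable, estimate_h2
from .synthetic import (
    CommunitySimConfig,
    PedigreeSimConfig,
    simulate_neutral_table,
    simulate_pedigree,
)

logger = logging.getLogger(__name__)

_STAGE_DEFAULTS: dict[str, dict[str, Any]] = {
    "demux": {
        "reads": None,
        "barcodes": None,
        "window": 100,
        "max_mismatches": 0,
        "min_len": 1000,
        "max_len": 2000,
        "search_revcomp": True,
    },
    "simulate_table": {
        "n_taxa": 1500,
        "n_samples": 60,
        "depth_mean": 15000.0,
        "depth_sd": 5500.0,
        "m_true": 0.05,
        "n_above": 0,
        "n_below": 0,
        "seed": 0,
    },
    "simulate_pedigree": {
        "n_families": 200,
        "h2_true": 0.2,
        "pheno_mean": 0.20,
        "pheno_sd": 0.03,
        "offspring_per_family": 10,
        "seed": 0,
    },
    "sncm": {
        "table": None,
        "metadata": None,
        "group_by": "sub_line",
        "alpha": 0.05,
        "d": None,
        "min_abundance": 0.01,
        "min_freq": 0.2,
        "min_deviation": 0.05,
        "literal_stage4": False,
    },
    "heritability": {"pedigree": None},
}


@dataclass
class RunConfig:
    out_dir: Path
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        out_dir = Path(raw.pop("out_dir", "neutralline_run"))
        log_level = raw.pop("log_level", "INFO")
        stage_raw = raw.pop("stages", {})
        if raw:
            raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
        stages: dict[str, dict[str, Any]] = {}
        for name, params in stage_raw.items():
            if name not in _STAGE_DEFAULTS:
                raise ValueError(f"unknown stage {name!r}; valid: {sorted(_STAGE_DEFAULTS)}")
            params = dict(params or {})
            unknown = set(params) - set(_STAGE_DEFAULTS[name])
            if unknown:
                raise ValueError(f"unknown keys in stage {name!r}: {sorted(unknown)}")
            merged = {**_STAGE_DEFAULTS[name], **params}
            stages[name] = merged
        return cls(out_dir=out_dir, stages=stages, log_level=log_level)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(stages: dict) -> str:
    return hashlib.sha256(json.dumps(stages, sort_keys=True, default=str).encode()).hexdigest()


# stage execution order; later stages may consume earlier outputs
_STAGE_ORDER = ("simulate_table", "simulate_pedigree", "demux", "sncm", "heritability")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory. The manifest lists, per stage, the parameters
    used and sha256 checksums of every file the stage wrote; a failure aborts
    with the stage name while preserving partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict[str, Any] = {
        "package": "neutralline",
        "version": __version__,
        "config_hash": _config_hash(config.stages),
        "stages": {},
    }
    table_path: Optional[Path] = None
    meta_path: Optional[Path] = None
    pedigree_path: Optional[Path] = None

    for name in _STAGE_ORDER:
        if name not in config.stages:
            continue
        params = config.stages[name]
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        logger.info("running stage %s", name)
        try:
            if name == "simulate_table":
                sim = CommunitySimConfig(**params)
                table, truth = simulate_neutral_table(sim)
                table_path = stage_dir / "feature_table.tsv"
                meta_path = stage_dir / "metadata.tsv"
                table.write_tsv(table_path, meta_path)
                truth.to_csv(stage_dir / "truth_labels.tsv", sep="\t")
            elif name == "simulate_pedigree":
                sim = PedigreeSimConfig(**params)
                ped = simulate_pedigree(sim)
                pedigree_path = stage_dir / "pedigree.tsv"
                ped.to_frame().to_csv(pedigree_path, sep="\t", index=False)
            elif name == "demux":
                if params["reads"] is None or params["barcodes"] is None:
                    raise ValueError("demux stage needs 'reads' and 'barcodes' paths")
                demux_fastq(
                    params["reads"],
                    params["barcodes"],
                    stage_dir,
                    window=params["window"],
                    max_mismatches=params["max_mismatches"],
                    min_len=params["min_len"],
                    max_len=params["max_len"],
                    search_revcomp=params["search_revcomp"],
                )
            elif name == "sncm":
                tpath = params["table"] or table_path
                mpath = params["metadata"] or meta_path
                if tpath is None:
                    raise ValueError("sncm stage needs a 'table' path or a simulate_table stage")
                table = FeatureTable.read_tsv(tpath, mpath)
                fc = FilterConfig(
                    min_abundance=params["min_abundance"],
                    min_freq=params["min_freq"],
                    min_deviation=params["min_deviation"],
                    literal_stage4=params["literal_stage4"],
                )
                group_by = params["group_by"] if mpath is not None else None
                recs, summary, _ = run_sncm(
                    table, group_by=group_by, d=params["d"], alpha=params["alpha"], filter_config=fc
                )
                recs.to_csv(stage_dir / "sncm_records.tsv", sep="\t", index=False)
                summary.to_csv(stage_dir / "sncm_summary.tsv", sep="\t", index=False)
            elif name == "heritability":
                ppath = params["pedigree"] or pedigree_path
                if ppath is None:
                    raise ValueError("heritability stage needs a 'pedigree' path or a simulate_pedigree stage")
                est = estimate_h2(PedigreeTable.read_tsv(ppath))
                with open(stage_dir / "heritability.json", "w") as fh:
                    json.dump(
                        {
                            "h2": est.h2,
                            "intercept": est.intercept,
                            "r_squared": est.r_squared,
                            "n_families": est.n_families,
                            "slope_se": est.slope_se,
                        },
                        fh,
                        indent=2,
                    )
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e

        manifest["stages"][name] = {
            "params": {k: str(v) if isinstance(v, Path) else v for k, v in params.items()},
            "outputs": {f.name: _sha256(f) for f in sorted(stage_dir.iterdir()) if f.is_file()},
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
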