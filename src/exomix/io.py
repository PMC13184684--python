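"""Canonical on-disk formats: TSV matrices/tables, GMT gene sets, JSON results.

TSV is tab-separated, UTF-8, ``.`` decimal; feature matrices are feature rows
by sample columns with the feature id in the first column. GMT follows the
standard layout (set name, description, members). Run configuration is YAML
with every threshold pre-filled to the analysis defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "write_gmt",
    "write_json",
]

_DEFAULT_THRESHOLDS = {
    "da_alpha": 0.05,
    "exerkine_alpha": 0.1,
    "cpm_threshold": 0.5,
    "cpm_sample_fraction": 0.10,
    "proteomics_min_quant": 0.30,
    "metabolomics_max_missing": 0.20,
    "cluster_threshold": 0.3,
    "min_set_size": 5,
    "min_set_retention": 0.70,
    "kinase_alpha": 0.1,
    "min_extracellular_score": 4.0,
    "edge_weight_cut": 0.1,
    "n_permutations": 100,
    "min_paired": 3,
    "camera_rho": 0.01,
}


@dataclass
class RunConfig:
    """Pipeline configuration: paths, thresholds, seeds, stage toggles."""

    seed: int = 0
    out_dir: str = "results"
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "da": True,
            "cluster": True,
            "enrich": True,
            "exerkine": True,
            "network": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"seed", "out_dir", "thresholds", "stages"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        thr = raw.get("thresholds", {})
        bad = set(thr) - set(_DEFAULT_THRESHOLDS)
        if bad:
            raise ValueError(f"unknown threshold keys: {sorted(bad)}")
        cfg.thresholds.update(thr)
        cfg.stages.update(raw.get("stages", {}))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "thresholds": self.thresholds, "stages": self.stages},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Features-by-samples TSV; first column holds feature ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()[:5]
        raise ValueError(f"duplicate feature ids: {list(dups)}")
    return df


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets; duplicate set names are an error."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT rows need name, description, members")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
        sets[name] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
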