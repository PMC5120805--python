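"""Dataset manifests, label policies, and run configuration.

A manifest is a CSV table with one row per clip: path, label, split
("train"/"test"), sensor, timestamp (ISO-8601).  Free-string labels are
mapped through a label policy onto the three monitoring annotation
categories — Target (the species of interest), FlightCall (calls of
other species) and Reject (no flight call) — mirroring how field
annotations collapse onto "target vs other".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

MANIFEST_COLUMNS = ("path", "label", "split", "sensor", "timestamp")
CATEGORIES = ("Target", "FlightCall", "Reject")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def validate_manifest(df: pd.DataFrame, label_set=None) -> None:
    if df["path"].duplicated().any():
        dupes = df.loc[df["path"].duplicated(), "path"].tolist()
        raise ValueError(f"duplicate clip paths in manifest: {dupes[:5]}")
    bad_split = set(df["split"]) - {"train", "test"}
    if bad_split:
        raise ValueError(f"unknown split values: {sorted(bad_split)}")
    if label_set is not None:
        unknown = set(df["label"]) - set(label_set)
        if unknown:
            raise ValueError(f"labels outside the declared label set: {sorted(unknown)}")


def summarize_manifest(
    df: pd.DataFrame, label_policy: dict[str, str] | None = None
) -> pd.DataFrame:
    """Dataset summary: per-split Target/FlightCall/Reject counts and %Pos.

    %Pos = 100 * Target / (FlightCall + Reject), one decimal — the
    positive count expressed as a percentage of the negatives (e.g.
    counts (882, 1063, 3071) summarize to 21.3%).
    """
    policy = label_policy or {c: c for c in CATEGORIES}
    unknown = set(df["label"]) - set(policy)
    if unknown:
        raise ValueError(f"labels without a policy mapping: {sorted(unknown)}")
    mapped = df["label"].map(policy)
    bad = set(mapped) - set(CATEGORIES)
    if bad:
        raise ValueError(f"label policy maps onto unknown categories: {sorted(bad)}")
    rows = []
    splits = list(dict.fromkeys(df["split"]))
    for split_name, sub in [(s, mapped[df["split"] == s]) for s in splits] + [
        ("total", mapped)
    ]:
        counts = {c: int((sub == c).sum()) for c in CATEGORIES}
        rows.append({"split": split_name, **counts, "pct_pos": pct_pos(**counts)})
    return pd.DataFrame(rows)


def pct_pos(Target: int, FlightCall: int, Reject: int) -> float:
    """Positives as a percentage of negatives, one decimal."""
    negatives = FlightCall + Reject
    if negatives == 0:
        raise ValueError("%Pos undefined without negative instances")
    return round(100.0 * Target / negatives, 1)


@dataclass
class RunConfig:
    """Serializable configuration for a CLI run (hash recorded in artifacts)."""

    scenario: str = "nclass"  # "nclass" | "monitoring"
    seed: int = 0
    frontend: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    output_dir: str = "runs"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "frontend": self.frontend,
            "grids": self.grids,
            "output_dir": self.output_dir,
            "extra": self.extra,
        }

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
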