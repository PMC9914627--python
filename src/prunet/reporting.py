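"""Run manifests and report rendering (tables + training curves)."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    timestamp: str = ""
    outputs: list = field(default_factory=list)
    dataset_hash: str | None = None

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def plot_histories(histories: dict[str, pd.DataFrame], out_path,
                   metric: str = "loss", ylabel: str = "Dice loss") -> Path:
    """Epoch-vs-metric curves for one or more runs (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in histories.items():
        if metric in df.columns:
            ax.plot(df["epoch"], df[metric], label=label)
    ax.set_xlabel("epoch")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def combine_run_tables(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """One comparison row per run, taken from each table's Average row."""
    rows = []
    for label, df in tables.items():
        avg = df[df["k-Fold"] == "Average"]
        if avg.empty:
            raise ValueError(f"run {label!r} has no Average row")
        row = {"Method": label, **avg.iloc[0].drop("k-Fold").to_dict()}
        rows.append(row)
    return pd.DataFrame(rows)
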