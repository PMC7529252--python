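"""Configuration parsing, table/sequence/image I/O and run manifests.

Scenario files are YAML (JSON is a subset) with the schema::

    name: xy_univalent_random          # optional
    mII_rule: random_chromatids        # or regular_sisters
    chromosomes:
      - name: XY
        conjunction: univalent_pair
        homologs:                      # explicit form (heteromorphic pairs)
          - {label: X, dna_content: 42.0, probe: red}
          - {label: Y, dna_content: 40.0, probe: green}
      - name: "2"
        conjunction: bivalent
        dna_content: 48.0              # shorthand: both homologs identical
        probe: none                    # shorthand probe sits on homolog a

Unknown keys are rejected at every level.  Output tables carry a header
comment recording the scenario hash and seed so every CSV is traceable
to the exact model and random stream that produced it.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO

from .errors import ConfigurationError
from .motifs import ProteinRecord
from .scenario import ChromosomeSpec, Homolog, MeiosisScenario

logger = logging.getLogger(__name__)

_SCENARIO_KEYS = {"name", "mII_rule", "chromosomes"}
_CHROM_KEYS = {"name", "conjunction", "dna_content", "probe", "homologs"}
_HOMOLOG_KEYS = {"label", "dna_content", "probe"}


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {unknown} in {context}; allowed: {sorted(allowed)}"
        )


def _parse_homolog(d: dict, default_label: str) -> Homolog:
    if not isinstance(d, dict):
        raise ConfigurationError(f"homolog entry must be a mapping, got {d!r}")
    _check_keys(d, _HOMOLOG_KEYS, "homolog")
    return Homolog(
        label=str(d.get("label", default_label)),
        dna_content=float(d.get("dna_content", 1.0)),
        probe=str(d.get("probe", "none")),
    )


def _parse_chromosome(d: dict) -> ChromosomeSpec:
    if not isinstance(d, dict):
        raise ConfigurationError(f"chromosome entry must be a mapping, got {d!r}")
    _check_keys(d, _CHROM_KEYS, "chromosome")
    if "name" not in d:
        raise ConfigurationError("chromosome entry is missing required key 'name'")
    if "conjunction" not in d:
        raise ConfigurationError(
            f"chromosome {d['name']!r} is missing required key 'conjunction'"
        )
    name = str(d["name"])
    if "homologs" in d:
        if "dna_content" in d or "probe" in d:
            raise ConfigurationError(
                f"chromosome {name!r}: give either 'homologs' or the "
                "flat 'dna_content'/'probe' shorthand, not both"
            )
        homs = d["homologs"]
        if not isinstance(homs, list) or len(homs) != 2:
            raise ConfigurationError(
                f"chromosome {name!r}: 'homologs' must list exactly 2 entries"
            )
        homologs = tuple(
            _parse_homolog(h, f"{name}{suffix}")
            for h, suffix in zip(homs, ("a", "b"))
        )
        return ChromosomeSpec(name=name, conjunction=str(d["conjunction"]), homologs=homologs)
    content = float(d.get("dna_content", 1.0))
    probe = str(d.get("probe", "none"))
    return ChromosomeSpec.pair(
        name,
        conjunction=str(d["conjunction"]),
        dna_content=content,
        probes=(probe, "none"),
    )


def scenario_from_dict(d: dict) -> MeiosisScenario:
    if not isinstance(d, dict):
        raise ConfigurationError("scenario config must be a mapping")
    _check_keys(d, _SCENARIO_KEYS, "scenario")
    if "chromosomes" not in d or not d["chromosomes"]:
        raise ConfigurationError("scenario config needs a non-empty 'chromosomes' list")
    return MeiosisScenario(
        chromosomes=tuple(_parse_chromosome(c) for c in d["chromosomes"]),
        mII_rule=str(d.get("mII_rule", "regular_sisters")),
        name=str(d.get("name", "scenario")),
    )


def parse_scenario(source: str | Path) -> MeiosisScenario:
    """Parse a scenario from YAML/JSON text or a file path."""
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"scenario config is not valid YAML/JSON: {exc}")
    return scenario_from_dict(data)


def write_scenario(scenario: MeiosisScenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    scenario: MeiosisScenario | None = None,
    seed: int | None = None,
) -> None:
    """Write a tidy CSV with a provenance header comment."""
    header = []
    if scenario is not None:
        header.append(f"# scenario={scenario.name} hash={scenario.hash()}")
    if seed is not None:
        header.append(f"# seed={seed}")
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_image(array: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), array)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ConfigurationError("more than 65535 labels; cannot write 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


# ---------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance of one CLI run: command, seeds, inputs, outputs."""

    command: str
    seeds: dict[str, int] = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    config_hash: str | None = None
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "seeds": self.seeds,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "timestamp": self.timestamp,
            "platform": platform.platform(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
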