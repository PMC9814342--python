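"""Readers, writers and run configuration.

All interchange formats are plain text: the pedigree file (animal sire dam),
a genotype table (animal id followed by 0/1/2 dosages), an optional
allele-frequency table, a phenotype table (animal, value, level), and CSV
tables for reliabilities, ERC weights and comparison reports.  Values are
written with 10 significant digits so write/read round trips are lossless at
the tolerances the method works to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic import GenotypeSet
from .mme import VarianceComponents
from .pipeline import METHODS, SCHEMES, ComparisonReport


class ConfigError(ValueError):
    pass


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_genotypes(path, freq_path=None) -> GenotypeSet:
    """Read a genotype table: first column animal id, then 0/1/2 dosages.

    Separator may be comma or whitespace; a header line is auto-detected
    (non-numeric dosage fields).  Missing dosages may be coded NA.
    """
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            body = fields[1:]
            if lineno == 1 and body and not all(
                _is_number(t) or t.upper() == "NA" for t in body
            ):
                continue  # header
            ids.append(fields[0])
            rows.append(
                [np.nan if t.upper() == "NA" else float(t) for t in body]
            )
    freq = read_frequencies(freq_path) if freq_path else None
    return GenotypeSet(animal_ids=ids, dosages=np.array(rows), allele_freq=freq)


def read_frequencies(path) -> np.ndarray:
    """Two-column (marker, frequency) table; returns frequencies in order."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ConfigError("frequency file needs columns marker, frequency")
    return df.iloc[:, 1].to_numpy(dtype=float)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table with columns animal, value, level."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = [c.lower() for c in df.columns]
    if set(("animal", "value", "level")) <= set(cols):
        df.columns = cols
    else:  # headerless
        df = pd.read_csv(
            path, sep=None, engine="python", header=None, comment="#"
        )
        if df.shape[1] < 3:
            raise ConfigError("phenotype file needs columns animal, value, level")
        df.columns = ["animal", "value", "level"] + [
            f"extra{i}" for i in range(df.shape[1] - 3)
        ]
    df["animal"] = df["animal"].astype(str)
    df["value"] = df["value"].astype(float)
    return df[["animal", "value", "level"]]


def write_value_table(path, animal_ids, values, tag: str) -> None:
    """CSV of (animal_id, value, tag) at 10 significant digits."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("animal_id,value,tag\n")
        for a, v in zip(animal_ids, values):
            fh.write(f"{a},{v:.10g},{tag}\n")


def read_value_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


# reliabilities and ERC share the same three-column layout
write_reliability_table = write_value_table
write_erc_table = write_value_table


def write_report(path, reports: list[ComparisonReport]) -> None:
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(
        path, index=False, float_format="%.10g"
    )


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run.

    Either the four input paths or a ``scenario`` section (parameters of the
    synthetic generator) must be present.  Unknown keys are rejected.
    """

    pedigree: str | None = None
    genotypes: str | None = None
    frequencies: str | None = None
    phenotypes: str | None = None
    reliabilities: str | None = None  # externally supplied Step-1 r2
    sigma2_u: float = 0.4
    sigma2_e: float = 0.6
    omega: float = 0.3
    method: str = "blended"
    scheme: str = "E"
    erc_floor: float = 0.01
    reverse_tol: float = 1e-5
    reverse_max_iter: int = 100
    compute_exact: bool = True
    seed: int = 1
    out_dir: str = "ssrel_out"
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.scheme not in SCHEMES:
            raise ConfigError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if not 0.0 <= self.omega <= 1.0:
            raise ConfigError(f"omega must be in [0, 1], got {self.omega}")
        if self.erc_floor <= 0:
            raise ConfigError("erc_floor must be positive")
        if self.reverse_tol <= 0:
            raise ConfigError("reverse_tol must be positive")
        if self.sigma2_u <= 0 or self.sigma2_e <= 0:
            raise ConfigError("variance components must be positive")

    @property
    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(
            sigma2_u=self.sigma2_u, sigma2_e=self.sigma2_e, omega=self.omega
        )

    def has_input_files(self) -> bool:
        return self.pedigree is not None and self.genotypes is not None


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
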