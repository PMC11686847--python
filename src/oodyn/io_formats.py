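"""Typed containers and strict tabular I/O for the pipeline.

All tables are UTF-8, tab-separated, with ``#``-prefixed comment lines
ignored and the first column serving as the id column.  Gene sets use the
GMT dialect (set name, description, then members, tab-separated).  Floating
output relies on Python's shortest-repr float formatting so that a write →
read round trip is the identity (bitwise for ids and categories, exact to
repr precision for floats).

Spike-in rows live in the same count matrix as endogenous genes and are
distinguished only by the ``is_spike_in`` flag: the quantification treats
them as rows of the same matrix, which is what lets them carry absolute
dosage information downstream.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STAGES = ("GV", "MII", "D3")
GENOTYPES = ("control", "mutant")


class ValidationError(ValueError):
    """Raised when an input table violates the documented contracts."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionExperiment:
    """Gene-level counts plus gene and sample metadata for a stage × genotype design.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes × samples.
    gene_meta
        Indexed by gene id; columns ``length`` (effective length, bases, > 0)
        and ``is_spike_in`` (bool).
    sample_meta
        Indexed by sample id; columns ``stage`` in {GV, MII, D3} and
        ``genotype`` in {control, mutant}.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        genes = self.counts.index
        samples = self.counts.columns
        _require_unique(genes, "gene id")
        _require_unique(samples, "sample id")
        missing_g = genes.difference(self.gene_meta.index)
        if len(missing_g):
            raise ValidationError(f"genes missing from gene metadata: {sorted(missing_g)[:10]}")
        extra_g = self.gene_meta.index.difference(genes)
        if len(extra_g):
            raise ValidationError(f"gene metadata rows absent from counts: {sorted(extra_g)[:10]}")
        missing_s = samples.difference(self.sample_meta.index)
        if len(missing_s):
            raise ValidationError(f"samples missing from sample metadata: {sorted(missing_s)[:10]}")
        extra_s = self.sample_meta.index.difference(samples)
        if len(extra_s):
            raise ValidationError(f"sample metadata rows absent from counts: {sorted(extra_s)[:10]}")
        self.gene_meta = self.gene_meta.loc[genes]
        self.sample_meta = self.sample_meta.loc[samples]

        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(vals < 0):
            g, s = np.argwhere(vals < 0)[0]
            raise ValidationError(f"negative count at gene {genes[g]!r}, sample {samples[s]!r}")
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
            raise ValidationError(f"non-integer count at gene {genes[g]!r}, sample {samples[s]!r}")
        self.counts = self.counts.astype(np.int64)

        if "length" not in self.gene_meta or "is_spike_in" not in self.gene_meta:
            raise ValidationError("gene metadata needs 'length' and 'is_spike_in' columns")
        if np.any(self.gene_meta["length"].to_numpy() <= 0):
            bad = self.gene_meta.index[self.gene_meta["length"] <= 0]
            raise ValidationError(f"non-positive gene length for: {sorted(bad)[:10]}")
        self.gene_meta["is_spike_in"] = self.gene_meta["is_spike_in"].astype(bool)

        for col, allowed in (("stage", STAGES), ("genotype", GENOTYPES)):
            if col not in self.sample_meta:
                raise ValidationError(f"sample metadata needs a '{col}' column")
            bad = set(self.sample_meta[col]) - set(allowed)
            if bad:
                raise ValidationError(f"unknown {col} label(s) {sorted(bad)}; allowed: {allowed}")

    # -- convenience --------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def is_spike_in(self) -> pd.Series:
        return self.gene_meta["is_spike_in"]

    @property
    def gene_length(self) -> pd.Series:
        return self.gene_meta["length"]

    @property
    def endogenous_ids(self) -> pd.Index:
        return self.counts.index[~self.is_spike_in.to_numpy()]

    @property
    def spike_ids(self) -> pd.Index:
        return self.counts.index[self.is_spike_in.to_numpy()]

    def samples_for(self, stage: str | None = None, genotype: str | None = None) -> pd.Index:
        mask = pd.Series(True, index=self.sample_ids)
        if stage is not None:
            mask &= self.sample_meta["stage"] == stage
        if genotype is not None:
            mask &= self.sample_meta["genotype"] == genotype
        return self.sample_ids[mask.to_numpy()]


@dataclass
class SpikeInReference:
    """Nominal spike-in amounts (identical absolute amount per sample)."""

    amounts: pd.Series  # indexed by spike id, positive

    def __post_init__(self) -> None:
        _require_unique(self.amounts.index, "spike id")
        if np.any(self.amounts.to_numpy() <= 0):
            bad = self.amounts.index[self.amounts <= 0]
            raise ValidationError(f"non-positive nominal amount for: {sorted(bad)[:10]}")
        self.amounts = self.amounts.astype(float)

    @property
    def spike_ids(self) -> pd.Index:
        return self.amounts.index

    def check_against(self, exp: ExpressionExperiment) -> None:
        """Every referenced spike present in the experiment must be flagged."""
        present = self.spike_ids.intersection(exp.gene_ids)
        unflagged = [g for g in present if not exp.is_spike_in[g]]
        if unflagged:
            raise ValidationError(
                f"spike ids present but not flagged is_spike_in: {unflagged[:10]}"
            )


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ProteinIntensityTable:
    """Protein × condition intensity matrix; conditions must include Vector, WT, Mut."""

    intensity: pd.DataFrame

    REQUIRED = ("Vector", "WT", "Mut")

    def __post_init__(self) -> None:
        _require_unique(self.intensity.index, "protein id")
        _require_unique(self.intensity.columns, "condition")
        missing = set(self.REQUIRED) - set(self.intensity.columns)
        if missing:
            raise ValidationError(f"missing required condition(s): {sorted(missing)}")
        vals = self.intensity.to_numpy(dtype=float)
        if np.any(vals < 0):
            p, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative intensity at protein {self.intensity.index[p]!r}, "
                f"condition {self.intensity.columns[c]!r}"
            )
        self.intensity = self.intensity.astype(float)

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensity.index


def _require_unique(index: Iterable, what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}(s): {dups[:10]}")
    if idx.isna().any():
        raise ValidationError(f"missing {what}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    if df.index.name is None and df.shape[1] == 0:
        raise ValidationError(f"{path}: no data columns found")
    df.index = df.index.astype(str)
    return df


def read_expression_experiment(
    counts_path: str | Path,
    gene_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> ExpressionExperiment:
    """Read and validate a counts matrix with gene and sample metadata.

    Spike-in rows are retained and flagged, never dropped.  Any id mismatch,
    duplicate, negative/non-integer count or unknown stage/genotype label
    raises :class:`ValidationError` naming the offenders; nothing is
    partially loaded.
    """
    counts = _read_table(counts_path)
    gene_meta = _read_table(gene_meta_path)
    sample_meta = _read_table(sample_meta_path)
    return ExpressionExperiment(counts=counts, gene_meta=gene_meta, sample_meta=sample_meta)


def read_spike_in_reference(path: str | Path) -> SpikeInReference:
    df = _read_table(path)
    if "nominal_amount" not in df:
        raise ValidationError(f"{path}: needs a 'nominal_amount' column")
    return SpikeInReference(amounts=df["nominal_amount"])


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>member...``.

    Duplicate members within a line are collapsed; a line with fewer than
    three fields or no members is a parse error reporting the line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, members=frozenset(members), description=desc))
    return sets


def read_protein_intensities(path: str | Path) -> ProteinIntensityTable:
    return ProteinIntensityTable(intensity=_read_table(path))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or index_label)


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def write_expression_experiment(exp: ExpressionExperiment, out_dir: str | Path) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": str(out / "counts.tsv"),
        "gene_meta": str(out / "genes.tsv"),
        "sample_meta": str(out / "samples.tsv"),
    }
    write_table(exp.counts, paths["counts"], index_label="gene_id")
    write_table(exp.gene_meta, paths["gene_meta"], index_label="gene_id")
    write_table(exp.sample_meta, paths["sample_meta"], index_label="sample_id")
    return paths


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    parameters: Mapping | None = None,
    inputs: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write each result table as TSV plus a JSON run manifest; return the manifest.

    Empty tables still produce a header-only file and are listed in the
    manifest, so a run's outputs are always enumerable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        write_table(df, path)
        written[name] = {"path": str(path), "rows": int(df.shape[0]), "columns": int(df.shape[1])}
    manifest = {
        "tables": written,
        "parameters": dict(parameters or {}),
        "inputs": dict(inputs or {}),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
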