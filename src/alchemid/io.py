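"""File I/O and run orchestration: SDF/SMILES in, scored SDF + CSV + JSON out.

SDF is the primary exchange format (it round-trips stereo annotations and
per-record properties); SMILES files (one per line, optional name column)
are accepted for convenience.  A pair run writes the intermediates as an
SDF with scores attached as properties, the score table as CSV, and a JSON
run report; a series run sweeps all unordered pairs and aggregates a
summary table plus series-level similarity statistics.

Naming convention: the parents of a pair are ``<pair>PA`` and ``<pair>PB``;
intermediates are ``<pair>I<n>`` with n counting from 0.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from rdkit import Chem

from .core_identification import McsConfig
from .enumeration import IntermediateSet, generate_intermediates
from .errors import AlchemidError, EmptyAfterFilter, ParseError
from .pruning import (
    PruneConfig,
    ScoreTable,
    rank_intermediates,
    summarize_pair,
    summarize_series,
)
from .records import MoleculeRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Reading and writing molecules
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        return "sdf"
    if suffix in (".smi", ".smiles", ".txt", ".csv"):
        return "smiles"
    raise ParseError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_molecules(path, fmt: Optional[str] = None) -> list[MoleculeRecord]:
    """Read sanitized molecule records from an SDF or SMILES file.

    Unparseable records are logged with their index and skipped; an empty
    file yields an empty list with a warning.  Raises ParseError when the
    file itself is missing or of unknown format.
    """
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"no such file: {path}")
    fmt = fmt or _infer_format(path)
    records: list[MoleculeRecord] = []
    n_failed = 0
    if path.stat().st_size == 0:
        logger.warning("%s: empty file, no molecules read", path.name)
        return records
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s: record %d unparseable, skipped", path.name, i)
                n_failed += 1
                continue
            records.append(MoleculeRecord.from_mol(mol))
    elif fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                logger.warning("%s: line %d unparseable, skipped", path.name, i + 1)
                n_failed += 1
                continue
            name = parts[1].strip() if len(parts) > 1 else f"mol{len(records)}"
            records.append(MoleculeRecord(mol=mol, name=name))
    else:
        raise ParseError(f"unknown format {fmt!r}")
    if not records:
        logger.warning("%s: no molecules read (%d failures)", path.name, n_failed)
    elif n_failed:
        logger.warning("%s: %d of %d records skipped", path.name, n_failed, n_failed + len(records))
    return records


def write_sdf(
    records: Sequence[MoleculeRecord],
    path,
    properties: Optional[dict[str, dict[str, object]]] = None,
) -> None:
    """Write records to an SDF; ``properties[name]`` maps extra SDF tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.name)
            for key, value in (properties or {}).get(rec.name, {}).items():
                mol.SetProp(str(key), str(value))
            writer.write(mol)
    finally:
        writer.close()


def write_smiles(records: Sequence[MoleculeRecord], path) -> None:
    Path(path).write_text(
        "".join(f"{r.canonical_form}\t{r.name}\n" for r in records)
    )


# ---------------------------------------------------------------------------
# Run report schema
# ---------------------------------------------------------------------------

_TYPE_CHECKS = {
    "string": str,
    "integer": int,
    "boolean": bool,
    "array": list,
    "object": dict,
}


def load_report_schema() -> dict:
    with resources.files("alchemid").joinpath("data/report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: Optional[dict] = None) -> None:
    """Check required keys and primitive types against the shipped schema;
    raises ValueError on violation."""
    schema = schema or load_report_schema()
    for key in schema.get("required", []):
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for key, spec in schema.get("properties", {}).items():
        if key in report:
            expected = _TYPE_CHECKS.get(spec.get("type"))
            if expected is not None and not isinstance(report[key], expected):
                raise ValueError(
                    f"report key {key!r} should be {spec['type']}, "
                    f"got {type(report[key]).__name__}"
                )


# ---------------------------------------------------------------------------
# Run configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pair or series run needs."""

    inputs: tuple[str, ...] = ()
    fmt: Optional[str] = None
    outdir: str = "."
    pair_id: Optional[str] = None
    mcs: McsConfig = field(default_factory=McsConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mcs = McsConfig(**raw.pop("mcs", {}))
        prune_raw = raw.pop("prune", {})
        for key in ("metrics", "weights"):
            if key in prune_raw and isinstance(prune_raw[key], list):
                prune_raw[key] = tuple(prune_raw[key])
        prune = PruneConfig(**prune_raw)
        if "inputs" in raw:
            raw["inputs"] = tuple(raw["inputs"])
        raw.update(overrides)
        return cls(mcs=mcs, prune=prune, **raw)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["mcs"] = dataclasses.asdict(self.mcs)
        out["prune"] = dataclasses.asdict(self.prune)
        out["inputs"] = list(self.inputs)
        out["prune"]["metrics"] = list(self.prune.metrics)
        out["prune"]["weights"] = list(self.prune.weights)
        return out


def _resolve_pair(cfg: RunConfig) -> tuple[MoleculeRecord, MoleculeRecord]:
    records: list[MoleculeRecord] = []
    for p in cfg.inputs:
        records.extend(read_molecules(p, cfg.fmt))
    if len(records) != 2:
        raise ParseError(f"pair mode needs exactly 2 molecules, got {len(records)}")
    return records[0], records[1]


def _score_one(
    iset: IntermediateSet, cfg: RunConfig
) -> tuple[Optional[ScoreTable], dict[str, dict[str, object]]]:
    if not iset.candidates:
        return None, {}
    score_table = rank_intermediates(iset, cfg.prune)
    props: dict[str, dict[str, object]] = {}
    for _, row in score_table.df.iterrows():
        props[row["name"]] = {
            c: row[c]
            for c in score_table.df.columns
            if c not in ("name", "canonical_form")
        }
    return score_table, props


def _run_one_pair(
    mol_a: MoleculeRecord, mol_b: MoleculeRecord, cfg: RunConfig, pair_id: str,
    outdir: Path,
) -> tuple[IntermediateSet, Optional[ScoreTable], dict]:
    """Shared pair pipeline: generate, score, write artifacts, build report."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    iset = generate_intermediates(mol_a, mol_b, cfg.mcs, pair_id=pair_id)
    timings["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    score_table, props = _score_one(iset, cfg)
    timings["score"] = time.perf_counter() - t0

    write_sdf(iset.candidates, outdir / f"{pair_id}_intermediates.sdf", props)
    if score_table is not None:
        score_table.to_csv(outdir / f"{pair_id}_scores.csv")

    report = {
        "pair_id": pair_id,
        "k": iset.table.n_differing,
        "n_candidates": len(iset.candidates),
        "n_failures": len(iset.failures),
        "parents_reconstructed": iset.parents_reconstructed,
        "candidates": [
            {
                "name": c.name,
                "smiles": c.canonical_form,
                "assignment": list(c.meta["assignment"]),
            }
            for c in iset.candidates
        ],
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "config": cfg.echo(),
    }
    validate_report(report)
    (outdir / f"{pair_id}_report.json").write_text(json.dumps(report, indent=2))
    if not iset.parents_reconstructed:
        logger.warning("pair %s flagged: parents were not regenerated", pair_id)
    return iset, score_table, report


def run_pair(cfg: RunConfig) -> dict:
    """Generate, score and write artifacts for one parent pair; returns the
    run report dict (also written as ``<pair>_report.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mol_a, mol_b = _resolve_pair(cfg)
    pair_id = cfg.pair_id or "pair"
    mol_a.name, mol_b.name = f"{pair_id}PA", f"{pair_id}PB"
    _iset, _table, report = _run_one_pair(mol_a, mol_b, cfg, pair_id, outdir)
    return report


def run_series(cfg: RunConfig) -> dict:
    """Run every unordered pair of a congeneric series; per-pair failures
    are recorded and the sweep continues.  Writes a per-pair summary CSV and
    series-level similarity statistics JSON; returns the stats dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: list[MoleculeRecord] = []
    for p in cfg.inputs:
        records.extend(read_molecules(p, cfg.fmt))
    if len(records) < 2:
        raise ParseError(f"series mode needs >= 2 molecules, got {len(records)}")
    for i, rec in enumerate(records):
        if not rec.name:
            rec.name = f"mol{i}"

    rows = []
    summaries = {m: [] for m in cfg.prune.metrics if m != "shape_color"}
    sets: list[IntermediateSet] = []
    for i, j in itertools.combinations(range(len(records)), 2):
        pair_id = f"{records[i].name}~{records[j].name}"
        row: dict[str, object] = {"pair_id": pair_id}
        try:
            iset, score_table, _report = _run_one_pair(
                records[i], records[j], cfg, pair_id, outdir
            )
            row.update(
                k=iset.table.n_differing,
                n_intermediates=len(iset.candidates),
                success=iset.parents_reconstructed,
            )
            if score_table is not None:
                best = score_table.ranked.iloc[0]
                row["best_candidate"] = best["name"]
                for metric in cfg.prune.metrics:
                    col = f"{metric}_combined"
                    if col in score_table.df.columns:
                        row[f"best_{col}"] = best[col]
            for metric in summaries:
                summaries[metric].append(summarize_pair(iset, metric, cfg.prune))
            sets.append(iset)
        except EmptyAfterFilter as exc:
            row.update(success=False, error=str(exc))
        except AlchemidError as exc:
            row.update(success=False, error=f"{type(exc).__name__}: {exc}")
        rows.append(row)

    summary_df = pd.DataFrame(rows)
    summary_df.to_csv(outdir / "series_summary.csv", index=False)
    stats = {
        "n_molecules": len(records),
        "n_pairs": len(rows),
        "n_success": int(summary_df.get("success", pd.Series(dtype=bool)).fillna(False).sum()),
        "n_intermediates_total": int(
            summary_df.get("n_intermediates", pd.Series(dtype=float)).fillna(0).sum()
        ),
        "similarity": {m: summarize_series(s) for m, s in summaries.items()},
    }
    (outdir / "series_stats.json").write_text(json.dumps(stats, indent=2))
    return stats
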