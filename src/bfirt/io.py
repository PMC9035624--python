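"""Readers and writers for the on-disk formats.

Matrices are CSV with persons as rows and items as columns (header row =
item identifiers); the loading pattern is a two-column TSV ``item_id,
group_id``; truth bundles, manifests and run configurations are JSON.
Times are stored in seconds (the log transform is internal), missing values
are empty cells, and all numbers are written at full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .models import LoadingPattern
from .simulate import TruthBundle

__all__ = ["DatasetBundle", "RunConfig", "read_dataset", "write_dataset",
           "read_truth", "write_truth"]


class DatasetValidationError(ValueError):
    """A dataset file violated the format contract."""


@dataclass(frozen=True)
class DatasetBundle:
    """A validated response/time/pattern triple ready for fitting."""

    U: np.ndarray                     # N x m, 0/1 with NaN for missing
    T: np.ndarray                     # N x m, seconds with NaN for missing
    pattern: LoadingPattern
    person_ids: List[str]
    item_ids: List[str]
    group_ids: List[str]              # original group labels, index = dim
    provenance: Dict[str, str] = field(default_factory=dict)

    @property
    def n_persons(self) -> int:
        return self.U.shape[0]

    @property
    def n_items(self) -> int:
        return self.U.shape[1]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_matrix(path: Path, name: str) -> pd.DataFrame:
    # check the raw header: pandas silently renames duplicate columns
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise DatasetValidationError(
            f"duplicate item id(s) {dups} in {name} header")
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise DatasetValidationError(f"cannot parse {name} file {path}: {exc}")
    df.columns = header
    return df


def read_dataset(responses_path, times_path, pattern_path) -> DatasetBundle:
    """Load and cross-validate a dataset.

    Raises :class:`DatasetValidationError` naming the offending cell for
    non-binary responses, non-numeric or non-positive times, duplicate item
    ids, items absent from the pattern, or items assigned to more than one
    group (the between-item restriction).
    """
    responses_path = Path(responses_path)
    times_path = Path(times_path)
    pattern_path = Path(pattern_path)
    rdf = _read_matrix(responses_path, "responses")
    tdf = _read_matrix(times_path, "times")
    item_ids = [str(c) for c in rdf.columns]
    if [str(c) for c in tdf.columns] != item_ids:
        raise DatasetValidationError(
            "times header does not match responses header")
    if len(tdf) != len(rdf):
        raise DatasetValidationError(
            f"responses have {len(rdf)} rows but times have {len(tdf)}")

    U = np.full(rdf.shape, np.nan)
    for j, col in enumerate(rdf.columns):
        for i, raw in enumerate(rdf[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
                continue
            if raw not in ("0", "1", "0.0", "1.0"):
                raise DatasetValidationError(
                    f"response row {i} item '{col}': '{raw}' is not 0/1/missing")
            U[i, j] = float(raw)

    T = np.full(tdf.shape, np.nan)
    for j, col in enumerate(tdf.columns):
        for i, raw in enumerate(tdf[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
                continue
            try:
                v = float(raw)
            except ValueError:
                raise DatasetValidationError(
                    f"time row {i} item '{col}': '{raw}' is not numeric")
            if not np.isfinite(v) or v <= 0:
                raise DatasetValidationError(
                    f"time row {i} item '{col}': {v} is not strictly positive")
            T[i, j] = v

    pdf = pd.read_csv(pattern_path, sep="\t", dtype=str)
    if list(pdf.columns[:2]) != ["item_id", "group_id"]:
        raise DatasetValidationError(
            "pattern file must have columns 'item_id' and 'group_id'")
    assignments: Dict[str, str] = {}
    for _, row in pdf.iterrows():
        it, gr = str(row["item_id"]), str(row["group_id"])
        if it in assignments:
            if assignments[it] != gr:
                raise DatasetValidationError(
                    f"item '{it}' assigned to groups '{assignments[it]}' and "
                    f"'{gr}' (items must load on exactly one specific dimension)")
            raise DatasetValidationError(f"item '{it}' listed twice in pattern")
        assignments[it] = gr
    missing = [it for it in item_ids if it not in assignments]
    if missing:
        raise DatasetValidationError(f"item(s) {missing} missing from pattern")

    group_ids: List[str] = []
    group_of = np.empty(len(item_ids), dtype=np.int64)
    for j, it in enumerate(item_ids):
        gr = assignments[it]
        if gr not in group_ids:
            group_ids.append(gr)
        group_of[j] = group_ids.index(gr)
    pattern = LoadingPattern(n_items=len(item_ids),
                             n_specific=len(group_ids), group_of=group_of)
    return DatasetBundle(
        U=U, T=T, pattern=pattern,
        person_ids=[str(i) for i in range(len(rdf))],
        item_ids=item_ids, group_ids=group_ids,
        provenance={
            "responses": str(responses_path), "times": str(times_path),
            "pattern": str(pattern_path),
            "responses_sha256": _sha256(responses_path),
            "times_sha256": _sha256(times_path),
            "pattern_sha256": _sha256(pattern_path),
        })


def write_dataset(out_dir, U: np.ndarray, T: np.ndarray,
                  pattern: LoadingPattern,
                  truth: Optional[TruthBundle] = None,
                  item_ids: Optional[List[str]] = None) -> Dict[str, Path]:
    """Write ``responses.csv``, ``times.csv``, ``pattern.tsv`` and
    optionally ``truth.json``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = pattern.n_items
    if item_ids is None:
        item_ids = [f"item{j + 1}" for j in range(m)]
    paths = {}
    rdf = pd.DataFrame(np.asarray(U, dtype=float), columns=item_ids)
    # responses as integers where observed, empty where missing
    rdf = rdf.map(lambda v: "" if np.isnan(v) else str(int(v)))
    paths["responses"] = out / "responses.csv"
    rdf.to_csv(paths["responses"], index=False)
    tdf = pd.DataFrame(np.asarray(T, dtype=float), columns=item_ids)
    tdf = tdf.map(lambda v: "" if np.isnan(v) else repr(float(v)))
    paths["times"] = out / "times.csv"
    tdf.to_csv(paths["times"], index=False)
    pdf = pd.DataFrame({
        "item_id": item_ids,
        "group_id": [f"g{g + 1}" for g in pattern.group_of],
    })
    paths["pattern"] = out / "pattern.tsv"
    pdf.to_csv(paths["pattern"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = write_truth(out / "truth.json", truth)
    return paths


def write_truth(path, truth: TruthBundle) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ALLOWED_KEYS = {
    "model": {"variant"},
    "priors": {"eta", "mu_d_loc", "mu_d_scale", "mu_beta_loc", "mu_beta_scale"},
    "sampler": {"chains", "iterations", "thin", "warmup_fraction", "seed",
                "target_accept", "max_treedepth", "psrf_threshold"},
    "simulation": {"N", "m", "n_specific", "group_sizes", "seed", "mu_d",
                   "mu_beta", "var_d", "var_beta", "cov_d_beta",
                   "rho_general", "rho_specific"},
    "study": {"conditions", "replications", "n_specific", "base_seed",
              "exclude_nonconverged"},
    "paths": {"responses", "times", "pattern", "out"},
}


@dataclass
class RunConfig:
    """Nested run configuration, JSON-serializable.

    Unknown sections or keys are rejected; a missing top-level ``seed`` is
    auto-filled (and echoed back on save) so that every run is replayable.
    """

    sections: Dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("run config must be a JSON object")
        seed = raw.pop("seed", None)
        for section, content in raw.items():
            if section not in _ALLOWED_KEYS:
                raise ValueError(f"unknown config section '{section}'")
            unknown = set(content) - _ALLOWED_KEYS[section]
            if unknown:
                raise ValueError(
                    f"unknown key(s) {sorted(unknown)} in section '{section}'")
        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] % (2 ** 31))
        return cls(sections=raw, seed=int(seed))

    def to_json(self, path) -> None:
        out = dict(self.sections)
        out["seed"] = self.seed
        Path(path).write_text(json.dumps(out, indent=1))
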