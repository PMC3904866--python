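"""Plain-text readers and writers for every pipeline artifact.

All artifacts are flat, diff-able text: tab-separated notes with escaped
internal newlines, a two-column ground-truth table, coordinate-triplet
sparse matrices with sidecar vocabulary and row files, prefix-notation
model expressions, JSON manifests for ensembles and CV reports, and a
YAML run configuration with strict (unknown keys rejected) validation.
Every writer has a reader that round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import corpus as _corpus
from .ensemble import Ensemble
from .features import FeatureMatrix, ClinicalNote, Vocabulary
from .gp import BooleanProgram, GPParams, TrainedModel
from .selection import PairFilterRules
from .evaluation import CVConfig, CVReport, FeatureReport, ScoreHistogram

log = logging.getLogger("notesignal")


class FormatError(ValueError):
    """Malformed artifact file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# --- notes and ground truth ------------------------------------------------

_NOTE_HEADER = "patient_id\tcohort\tdate\ttext"


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"n": "\n", "t": "\t", "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def write_notes(notes: Iterable[ClinicalNote], path) -> None:
    """One record per note; text newlines/tabs are backslash-escaped."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_NOTE_HEADER + "\n")
        for n in notes:
            cohort = "" if n.cohort is None else str(n.cohort)
            fh.write(
                f"{n.patient_id}\t{cohort}\t{n.date.isoformat()}\t{_escape(n.text)}\n"
            )


def read_notes(path) -> list[ClinicalNote]:
    """Parse the note record format; malformed lines report their number."""
    path = Path(path)
    notes: list[ClinicalNote] = []
    with path.open() as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        log.warning("%s: empty notes file", path)
        return notes
    if lines[0] != _NOTE_HEADER:
        raise FormatError(path, 1, f"expected header {_NOTE_HEADER!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(path, lineno, f"expected 4 fields, got {len(parts)}")
        pid, cohort_s, date_s, text = parts
        if not pid:
            raise FormatError(path, lineno, "empty patient_id")
        try:
            cohort = int(cohort_s) if cohort_s else None
            date = _dt.date.fromisoformat(date_s)
            notes.append(ClinicalNote(pid, cohort, date, _unescape(text)))
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
    if not notes:
        log.warning("%s: notes file has a header but no records", path)
    return notes


def write_truth(labels: dict[str, int], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("patient_id\tcohort\n")
        for pid in sorted(labels):
            fh.write(f"{pid}\t{labels[pid]}\n")


def read_truth(path) -> dict[str, int]:
    path = Path(path)
    out: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1:
                if line != "patient_id\tcohort":
                    raise FormatError(path, 1, "bad ground-truth header")
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(path, lineno, "expected 2 fields")
            try:
                out[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
    return out


# --- feature matrices ------------------------------------------------------

def write_matrix(matrix: FeatureMatrix, prefix) -> None:
    """Write <prefix>.triplets.tsv, <prefix>.vocab.tsv, <prefix>.rows.tsv."""
    prefix = Path(prefix)
    coo = matrix.counts.tocoo()
    with open(f"{prefix}.triplets.tsv", "w") as fh:
        fh.write("row_id\tfeature_index\tcount\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{matrix.row_ids[i]}\t{j}\t{v}\n")
    with open(f"{prefix}.vocab.tsv", "w") as fh:
        fh.write(f"# kind={matrix.vocab.kind}\nindex\tfeature\n")
        for j, name in enumerate(matrix.vocab.names):
            fh.write(f"{j}\t{name}\n")
    with open(f"{prefix}.rows.tsv", "w") as fh:
        fh.write("row_id\tcohort\n")
        for i, rid in enumerate(matrix.row_ids):
            lab = "" if matrix.labels is None else str(int(matrix.labels[i]))
            fh.write(f"{rid}\t{lab}\n")


def read_matrix(prefix) -> FeatureMatrix:
    prefix = Path(prefix)
    with open(f"{prefix}.vocab.tsv") as fh:
        kind_line = fh.readline().strip()
        kind = kind_line.split("=", 1)[1] if "=" in kind_line else "unigram"
        fh.readline()  # column header
        names = tuple(line.rstrip("\n").split("\t")[1] for line in fh if line.strip())
    rows_frame = pd.read_csv(f"{prefix}.rows.tsv", sep="\t", dtype={"row_id": str})
    row_ids = tuple(rows_frame["row_id"])
    labels = None
    if rows_frame["cohort"].notna().all() and len(rows_frame):
        labels = rows_frame["cohort"].astype(int).to_numpy()
    trip = pd.read_csv(f"{prefix}.triplets.tsv", sep="\t", dtype={"row_id": str})
    row_index = {r: i for i, r in enumerate(row_ids)}
    counts = sp.csr_matrix(
        (
            trip["count"].to_numpy(),
            (
                trip["row_id"].map(row_index).to_numpy(dtype=np.int64)
                if len(trip)
                else np.array([], dtype=np.int64),
                trip["feature_index"].to_numpy(dtype=np.int64)
                if len(trip)
                else np.array([], dtype=np.int64),
            ),
        ),
        shape=(len(row_ids), len(names)),
        dtype=np.int64,
    )
    return FeatureMatrix(row_ids, Vocabulary(names, kind), counts, labels)


# --- MI tables and feature reports -----------------------------------------

def write_mi_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_mi_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_feature_report(report: FeatureReport, out_dir) -> None:
    """Per-cohort ``cohort<label>_terms.tsv`` (term, frequency) lists."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for cohort, terms in sorted(report.cohorts.items()):
        with (out_dir / f"cohort{cohort}_terms.tsv").open("w") as fh:
            fh.write("term\tfrequency\n")
            for term, freq in terms:
                fh.write(f"{term}\t{freq}\n")
    with (out_dir / "dropped_ties.txt").open("w") as fh:
        fh.write("\n".join(report.dropped_ties) + ("\n" if report.dropped_ties else ""))


# --- models and ensembles --------------------------------------------------

def write_model(model: TrainedModel, path, feature_names: Sequence[str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# seed={model.seed} task={model.task} ")
        fh.write(f"fitness={model.fitness:.6f} accuracy={model.accuracy:.6f}\n")
        fh.write(model.program.to_text(feature_names) + "\n")


def read_model(path, feature_names: Sequence[str] | None = None) -> TrainedModel:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        expr = fh.readline().strip()
    meta = dict(
        kv.split("=", 1) for kv in header.lstrip("# ").split() if "=" in kv
    )
    return TrainedModel(
        program=BooleanProgram.parse(expr, feature_names),
        fitness=float(meta.get("fitness", "nan")),
        accuracy=float(meta.get("accuracy", "nan")),
        seed=int(meta.get("seed", "0")),
        task=meta.get("task", ""),
    )


def write_ensemble(ensemble: Ensemble, out_dir) -> None:
    """Directory of model files plus a JSON manifest and feature list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "task": ensemble.task,
        "n_models": len(ensemble),
        "seeds": ensemble.seeds(),
        "vote_rule": "majority, ties to positive class"
        if ensemble.tie_break == 1
        else "majority, ties to negative class",
        "features_file": "features.tsv",
        "model_files": [f"model_{i:03d}.txt" for i in range(len(ensemble))],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    with (out_dir / "features.tsv").open("w") as fh:
        fh.write("index\tfeature\n")
        for j, name in enumerate(ensemble.feature_names):
            fh.write(f"{j}\t{name}\n")
    for i, model in enumerate(ensemble.models):
        write_model(model, out_dir / f"model_{i:03d}.txt", ensemble.feature_names)


def read_ensemble(out_dir) -> Ensemble:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    names: list[str] = []
    with (out_dir / manifest["features_file"]).open() as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                names.append(line.rstrip("\n").split("\t")[1])
    models = tuple(
        read_model(out_dir / f, names) for f in manifest["model_files"]
    )
    tie = 1 if "positive" in manifest.get("vote_rule", "positive") else 0
    return Ensemble(models, manifest["task"], tuple(names), tie_break=tie)


# --- CV reports ------------------------------------------------------------

def write_cv_report(report: CVReport, out_dir) -> None:
    """report.json (summary + folds) plus a flat per-model score table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report.summary()
    payload["fold_test_ids"] = report.fold_test_ids
    payload["ensemble_scores"] = report.ensemble_scores
    payload["pair_filter_reports"] = report.pair_filter_reports
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
    with (out_dir / "model_scores.tsv").open("w") as fh:
        fh.write("task\tfold\tmodel\tholdout_accuracy\n")
        for task in sorted(report.model_scores):
            for fold, scores in enumerate(report.model_scores[task]):
                for i, s in enumerate(scores):
                    fh.write(f"{task}\t{fold}\t{i}\t{s:.6f}\n")


def write_histogram(hist: ScoreHistogram, path) -> None:
    hist.to_frame().to_csv(path, sep="\t", index=False)


# --- run configuration -----------------------------------------------------

def _from_mapping(cls, data: dict, where: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    fields = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where} section")
    return cls(**data)


@dataclasses.dataclass
class RunConfig:
    """Validated top-level configuration for the CLI pipeline."""

    generator: _corpus.GeneratorConfig
    cv: CVConfig
    pair_mode: str = "adjacent"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"generator", "featurization", "selection", "gp", "ensemble", "evaluation"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level config section(s) {sorted(unknown)}")

        gen_data = dict(data.get("generator", {}))
        profiles = gen_data.pop("profiles", None)
        gen_fields = {f.name for f in dataclasses.fields(_corpus.GeneratorConfig)}
        unknown = set(gen_data) - gen_fields
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in generator section")
        if "signature_rank_range" in gen_data:
            gen_data["signature_rank_range"] = tuple(gen_data["signature_rank_range"])
        if profiles is None:
            gen = dataclasses.replace(
                _corpus.default_config(), **gen_data
            ) if gen_data else _corpus.default_config()
        else:
            built = tuple(
                _from_mapping(
                    _corpus.CohortProfile,
                    {
                        **p,
                        "signature_terms": p.get(
                            "signature_terms",
                            {
                                t: _corpus._enrichment_from_hint(f)
                                for t, f in {
                                    1: _corpus._COHORT1_HINTS,
                                    2: _corpus._COHORT2_HINTS,
                                    3: _corpus._COHORT3_HINTS,
                                }.get(p["label"], {}).items()
                            },
                        ),
                    },
                    "generator.profiles",
                )
                for p in profiles
            )
            gen = _from_mapping(
                _corpus.GeneratorConfig,
                {**gen_data, "profiles": built},
                "generator",
            )

        feat = dict(data.get("featurization", {}))
        sel = dict(data.get("selection", {}))
        gp_data = dict(data.get("gp", {}))
        ens = dict(data.get("ensemble", {}))
        ev = dict(data.get("evaluation", {}))

        for section, allowed in (
            (feat, {"feature_kind", "pair_mode", "binarize_threshold", "strip_table_lines"}),
            (sel, {"select_k", "seed_top_m", "min_doc_freq", "mi_floor", "alpha", "bh_correct"}),
            (ens, {"n_models", "base_seed"}),
            (ev, {"k", "stratified", "seed", "dry_run"}),
        ):
            unknown = set(section) - allowed
            if unknown:
                raise ValueError(f"unknown config key(s) {sorted(unknown)}")

        gp = _from_mapping(GPParams, gp_data, "gp")
        rules = _from_mapping(
            PairFilterRules,
            {k: v for k, v in sel.items() if k != "select_k"},
            "selection",
        )
        cv = CVConfig(
            k=ev.get("k", 5),
            stratified=ev.get("stratified", True),
            seed=ev.get("seed", 0),
            feature_kind=feat.get("feature_kind", "unigram"),
            pair_mode=feat.get("pair_mode", "adjacent"),
            select_k=sel.get("select_k", 2000),
            binarize_threshold=feat.get("binarize_threshold", 1),
            pair_rules=rules,
            gp=gp,
            n_models=ens.get("n_models", 100),
            base_seed=ens.get("base_seed", 1000),
            dry_run=ev.get("dry_run", False),
            strip_table_lines=feat.get("strip_table_lines", False),
        )
        cfg = cls(generator=gen, cv=cv, pair_mode=feat.get("pair_mode", "adjacent"))
        cfg.generator.validate()
        cfg.cv.validate()
        return cfg


def load_run_config(path_or_default: str | Path) -> RunConfig:
    """Load a YAML run config; the literal string ``default`` is built in."""
    if str(path_or_default) == "default":
        return RunConfig.from_dict({})
    text = Path(path_or_default).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("run config must be a mapping")
    return RunConfig.from_dict(data)


def config_hash(path_or_default: str | Path) -> str:
    """Stable hash of the configuration content, for run logs."""
    if str(path_or_default) == "default":
        payload = b"default"
    else:
        payload = Path(path_or_default).read_bytes()
    return hashlib.sha256(payload).hexdigest()[:12]
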