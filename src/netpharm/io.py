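"""Readers, writers and validation for the study's tabular inputs.

All tables are UTF-8 text with a header row. The delimiter is inferred from
the file extension (``.tsv``/``.tab`` -> tab, otherwise comma) and can be
overridden per call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    SYSTEMS,
    Biomarker,
    DockingScoreMatrix,
    Enzyme,
    Pathway,
    StudyBundle,
    TargetProtein,
)

__all__ = [
    "StudyInputError",
    "Issue",
    "read_study_inputs",
    "validate_study",
    "write_study_bundle",
]

_HMDB_RE = re.compile(r"^HMDB\d{7}$")
_UNIPROT_RE = re.compile(r"^[A-NR-Z][0-9][A-Z][A-Z0-9]{2}[0-9]$|^[OPQ][0-9][A-Z0-9]{3}[0-9]$")
_HSA_RE = re.compile(r"^hsa\d{5}$")


class StudyInputError(ValueError):
    """A table could not be read or cross-referenced.

    Carries the file, row number (1-based, data rows) and offending value
    when known.
    """

    def __init__(self, message: str, *, file: str | Path | None = None,
                 row: int | None = None, value: object = None) -> None:
        self.file = str(file) if file is not None else None
        self.row = row
        self.value = value
        parts = [message]
        if file is not None:
            parts.append(f"[file={file}]")
        if row is not None:
            parts.append(f"[row={row}]")
        if value is not None:
            parts.append(f"[value={value!r}]")
        super().__init__(" ".join(parts))


@dataclass(frozen=True, slots=True, order=True)
class Issue:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    code: str
    message: str


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read_table(path: str | Path, required: Sequence[str],
                delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise StudyInputError("input file not found", file=path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str,
                     keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StudyInputError(
            f"missing required column(s) {missing}; found {list(df.columns)}",
            file=path,
        )
    return df

def _check_unique(ids: Iterable[str], kind: str, path: Path) -> None:
    seen: set[str] = set()
    for row, i in enumerate(ids, start=1):
        if i in seen:
            raise StudyInputError(f"duplicate {kind} id", file=path, row=row, value=i)
        seen.add(i)


def _split_multi(cell: str) -> frozenset[str]:
    return frozenset(s.strip() for s in cell.split(";") if s.strip())


def read_biomarkers(path: str | Path, delimiter: str | None = None) -> dict[str, Biomarker]:
    df = _read_table(path, ["id", "name", "platform", "trend"], delimiter)
    _check_unique(df["id"], "biomarker", Path(path))
    out: dict[str, Biomarker] = {}
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            out[rec.id] = Biomarker(rec.id, rec.name, rec.platform, rec.trend)
        except ValueError as e:
            raise StudyInputError(str(e), file=path, row=row, value=rec.id) from e
    return out


def read_enzymes(path: str | Path, delimiter: str | None = None) -> dict[str, Enzyme]:
    df = _read_table(path, ["id", "name", "functions"], delimiter)
    _check_unique(df["id"], "enzyme", Path(path))
    return {
        rec.id: Enzyme(rec.id, rec.name, _split_multi(rec.functions))
        for rec in df.itertuples(index=False)
    }


def read_relations(path: str | Path, delimiter: str | None = None) -> list[tuple[str, str]]:
    df = _read_table(path, ["biomarker_id", "enzyme_id"], delimiter)
    return [(rec.biomarker_id, rec.enzyme_id) for rec in df.itertuples(index=False)]


def read_targets(path: str | Path, delimiter: str | None = None) -> dict[str, TargetProtein]:
    df = _read_table(path, ["id", "name", "systems"], delimiter)
    _check_unique(df["id"], "target", Path(path))
    out: dict[str, TargetProtein] = {}
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            out[rec.id] = TargetProtein(rec.id, rec.name, _split_multi(rec.systems))
        except ValueError as e:
            raise StudyInputError(str(e), file=path, row=row, value=rec.id) from e
    return out


def read_pathways(path: str | Path, delimiter: str | None = None) -> dict[str, Pathway]:
    """Read the one-membership-per-row pathway table."""
    df = _read_table(path, ["pathway_id", "pathway_name", "target_id"], delimiter)
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for rec in df.itertuples(index=False):
        members.setdefault(rec.pathway_id, set()).add(rec.target_id)
        names.setdefault(rec.pathway_id, rec.pathway_name)
    return {
        pid: Pathway(pid, names[pid], frozenset(mem)) for pid, mem in members.items()
    }


def read_scores_long(path: str | Path, delimiter: str | None = None) -> DockingScoreMatrix:
    df = _read_table(path, ["biomarker_id", "target_id", "pkd"], delimiter)
    bids = sorted(df["biomarker_id"].unique())
    tids = sorted(df["target_id"].unique())
    brow = {b: i for i, b in enumerate(bids)}
    tcol = {t: j for j, t in enumerate(tids)}
    grid = np.full((len(bids), len(tids)), np.nan)
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.pkd == "":
            continue
        try:
            v = float(rec.pkd)
        except ValueError as e:
            raise StudyInputError("pkd is not numeric", file=path, row=row,
                                  value=rec.pkd) from e
        if not np.isfinite(v) or v < 0:
            raise StudyInputError(
                "pkd must be finite and >= 0", file=path, row=row, value=v)
        if not np.isnan(grid[brow[rec.biomarker_id], tcol[rec.target_id]]):
            raise StudyInputError(
                "duplicate (biomarker, target) score entry", file=path, row=row,
                value=(rec.biomarker_id, rec.target_id))
        grid[brow[rec.biomarker_id], tcol[rec.target_id]] = v
    return DockingScoreMatrix(bids, tids, grid)


def read_scores_wide(path: str | Path, delimiter: str | None = None) -> DockingScoreMatrix:
    path = Path(path)
    if not path.is_file():
        raise StudyInputError("input file not found", file=path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), encoding="utf-8")
    if df.columns[0] != "biomarker_id":
        raise StudyInputError(
            f"first column must be 'biomarker_id', got {df.columns[0]!r}", file=path)
    bids = [str(b) for b in df["biomarker_id"]]
    _check_unique(bids, "biomarker", path)
    tids = [str(c) for c in df.columns[1:]]
    grid = df.iloc[:, 1:].to_numpy(dtype=float)
    # canonicalize to sorted-id order so wide and long forms compare equal
    border = np.argsort(bids)
    torder = np.argsort(tids)
    return DockingScoreMatrix(
        [bids[i] for i in border], [tids[j] for j in torder],
        grid[np.ix_(border, torder)],
    )


def read_study_inputs(
    biomarkers: str | Path,
    enzymes: str | Path | None = None,
    relations: str | Path | None = None,
    targets: str | Path | None = None,
    scores: str | Path | None = None,
    pathways: str | Path | None = None,
    *,
    scores_form: str = "auto",
    delimiter: str | None = None,
) -> StudyBundle:
    """Load and cross-reference a study bundle from tabular files.

    ``scores_form`` is 'long', 'wide' or 'auto' (sniff from the header).
    Raises :class:`StudyInputError` on any unresolvable reference.
    """
    bundle = StudyBundle(biomarkers=read_biomarkers(biomarkers, delimiter))
    if enzymes is not None:
        bundle.enzymes = read_enzymes(enzymes, delimiter)
    if relations is not None:
        bundle.relations = read_relations(relations, delimiter)
        for row, (b, e) in enumerate(bundle.relations, start=1):
            if b not in bundle.biomarkers:
                raise StudyInputError("relation names unknown biomarker id",
                                      file=relations, row=row, value=b)
            if e not in bundle.enzymes:
                raise StudyInputError("relation names unknown enzyme id",
                                      file=relations, row=row, value=e)
    if targets is not None:
        bundle.targets = read_targets(targets, delimiter)
    if scores is not None:
        form = scores_form
        if form == "auto":
            head = pd.read_csv(Path(scores), sep=_delimiter_for(Path(scores), delimiter),
                               nrows=0, encoding="utf-8")
            form = "long" if list(head.columns[:3]) == ["biomarker_id", "target_id", "pkd"] else "wide"
        if form == "long":
            bundle.scores = read_scores_long(scores, delimiter)
        elif form == "wide":
            bundle.scores = read_scores_wide(scores, delimiter)
        else:
            raise StudyInputError(f"unknown scores_form {scores_form!r}", file=scores)
        for b in bundle.scores.biomarker_ids:
            if b not in bundle.biomarkers:
                raise StudyInputError("score matrix names unknown biomarker id",
                                      file=scores, value=b)
        if bundle.targets:
            for t in bundle.scores.target_ids:
                if t not in bundle.targets:
                    raise StudyInputError("score matrix names unknown target id",
                                          file=scores, value=t)
    if pathways is not None:
        bundle.pathways = read_pathways(pathways, delimiter)
        if bundle.targets:
            for pw in bundle.pathways.values():
                for t in sorted(pw.members):
                    if t not in bundle.targets:
                        raise StudyInputError(
                            f"pathway {pw.id} names unknown target id",
                            file=pathways, value=t)
    return bundle


def validate_study(bundle: StudyBundle) -> list[Issue]:
    """Check a bundle's invariants; returns a deterministic issue list.

    Never raises: every finding, including accession-shape mismatches
    (warnings, not errors), is reported as an :class:`Issue`.
    """
    issues: list[Issue] = []

    def err(code: str, message: str) -> None:
        issues.append(Issue("error", code, message))

    def warn(code: str, message: str) -> None:
        issues.append(Issue("warning", code, message))

    for b in bundle.biomarkers.values():
        if not _HMDB_RE.match(b.id):
            warn("accession-shape", f"biomarker id {b.id!r} is not HMDB-shaped")
    for e in bundle.enzymes.values():
        if not _UNIPROT_RE.match(e.id):
            warn("accession-shape", f"enzyme id {e.id!r} is not UniProt-shaped")
    for t in bundle.targets.values():
        if not _UNIPROT_RE.match(t.id):
            warn("accession-shape", f"target id {t.id!r} is not UniProt-shaped")
        extra = set(t.systems) - set(SYSTEMS)
        if extra:
            err("unknown-system",
                f"target {t.id} has system label(s) outside {SYSTEMS}: {sorted(extra)}")
        if not t.systems:
            err("empty-systems", f"target {t.id} belongs to no system")
    for p in bundle.pathways.values():
        if not _HSA_RE.match(p.id):
            warn("accession-shape", f"pathway id {p.id!r} is not hsaNNNNN-shaped")
        if not p.members:
            err("empty-pathway", f"pathway {p.id} has no member targets")

    for b, e in bundle.relations:
        if b not in bundle.biomarkers:
            err("dangling-relation", f"relation biomarker {b!r} not in catalog")
        if e not in bundle.enzymes:
            err("dangling-relation", f"relation enzyme {e!r} not in catalog")

    if bundle.scores is not None:
        s = bundle.scores.scores
        bad = np.argwhere(~np.isnan(s) & ((s < 0) | ~np.isfinite(s)))
        for i, j in bad.tolist():
            err("bad-score",
                f"score at ({bundle.scores.biomarker_ids[i]}, "
                f"{bundle.scores.target_ids[j]}) = {s[i, j]} is negative or non-finite")
        for b in bundle.scores.biomarker_ids:
            if bundle.biomarkers and b not in bundle.biomarkers:
                err("dangling-score-id", f"score-matrix biomarker {b!r} not in catalog")
        for t in bundle.scores.target_ids:
            if bundle.targets and t not in bundle.targets:
                err("dangling-score-id", f"score-matrix target {t!r} not in catalog")

    if bundle.targets:
        for pw in bundle.pathways.values():
            for t in sorted(pw.members - set(bundle.targets)):
                err("dangling-member", f"pathway {pw.id} member {t!r} not in target catalog")

    related = {b for b, _ in bundle.relations}
    for b in bundle.biomarkers:
        if bundle.relations and b not in related:
            warn("unrelated-biomarker", f"biomarker {b} has no enzyme relations")
    in_pathway = set().union(*(p.members for p in bundle.pathways.values())) \
        if bundle.pathways else set()
    for t in bundle.targets:
        if bundle.pathways and t not in in_pathway:
            warn("orphan-target", f"target {t} belongs to no pathway")

    order = {"error": 0, "warning": 1}
    issues.sort(key=lambda i: (order[i.severity], i.code, i.message))
    return issues


def write_study_bundle(bundle: StudyBundle, out_dir: str | Path,
                       *, delimiter: str = ",", scores_form: str = "long") -> dict[str, Path]:
    """Write every populated bundle table under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if delimiter == "\t" else ".csv"
    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}{ext}"
        df.to_csv(p, sep=delimiter, index=False, encoding="utf-8")
        paths[name] = p

    save("biomarkers", pd.DataFrame(
        [(b.id, b.name, b.platform, b.trend)
         for b in sorted(bundle.biomarkers.values(), key=lambda x: x.id)],
        columns=["id", "name", "platform", "trend"]))
    if bundle.enzymes:
        save("enzymes", pd.DataFrame(
            [(e.id, e.name, ";".join(sorted(e.functions)))
             for e in sorted(bundle.enzymes.values(), key=lambda x: x.id)],
            columns=["id", "name", "functions"]))
    if bundle.relations:
        save("relations", pd.DataFrame(sorted(bundle.relations),
                                       columns=["biomarker_id", "enzyme_id"]))
    if bundle.targets:
        save("targets", pd.DataFrame(
            [(t.id, t.name, ";".join(s for s in SYSTEMS if s in t.systems))
             for t in sorted(bundle.targets.values(), key=lambda x: x.id)],
            columns=["id", "name", "systems"]))
    if bundle.scores is not None:
        if scores_form == "long":
            save("scores_long", pd.DataFrame(
                sorted(bundle.scores.iter_present()),
                columns=["biomarker_id", "target_id", "pkd"]))
        else:
            df = pd.DataFrame(bundle.scores.scores,
                              columns=bundle.scores.target_ids)
            df.insert(0, "biomarker_id", bundle.scores.biomarker_ids)
            save("scores_wide", df)
    if bundle.pathways:
        rows = [(p.id, p.name, t)
                for p in sorted(bundle.pathways.values(), key=lambda x: x.id)
                for t in sorted(p.members)]
        save("pathways", pd.DataFrame(
            rows, columns=["pathway_id", "pathway_name", "target_id"]))
    return paths
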