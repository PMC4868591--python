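"""Directory-level sorting: classify every tree file, then move, copy
or merely list the hits into the output layout.

Layout (modes ``m``/``c`` only; ``l`` touches nothing but the log)::

    in_dir/<out_dir>/Exclusive/
    in_dir/<out_dir>/Exclusive/All_Exclusive/
    in_dir/<out_dir>/Non_Exclusive/
    in_dir/<out_dir>.log          # written in every mode

A file carrying both Exclusive and Non-Exclusive labels is relocated
under ``Exclusive/`` (a file can occupy one place); the log still
records every qualifying clade.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .clade_engine import (
    ALL_EXCLUSIVE,
    EXCLUSIVE,
    FAMILY_EXCLUSIVE,
    FAMILY_NON_EXCLUSIVE,
    NON_EXCLUSIVE,
    SortCriteria,
    TargetSpec,
    TreeClassification,
    classify_tree,
)
from .tree_io import NewickParseError, format_number, parse_tree

__all__ = ["SortJob", "SortReport", "SortJobError", "sort_trees", "write_log"]

logger = logging.getLogger(__name__)

MODE_MOVE = "m"
MODE_COPY = "c"
MODE_LIST = "l"

_LOG_COLUMNS = (
    "file",
    "tag",
    "support",
    "n_target",
    "n_nontarget",
    "prop_within",
    "prop_of_tree_targets",
    "leaves",
)


class SortJobError(ValueError):
    """Fatal misconfiguration of a sorting job."""


@dataclass(frozen=True)
class SortJob:
    in_dir: Path
    targets: TargetSpec
    criteria: SortCriteria = field(default_factory=SortCriteria)
    out_dir: str = "Sorted_Trees"
    mode: str = MODE_LIST
    extension: str = ".tre"

    def __post_init__(self) -> None:
        object.__setattr__(self, "in_dir", Path(self.in_dir))
        if self.mode not in (MODE_MOVE, MODE_COPY, MODE_LIST):
            raise SortJobError(f"mode must be one of 'm', 'c', 'l'; got {self.mode!r}")
        if not self.extension:
            raise SortJobError("extension must be non-empty")


@dataclass
class SortReport:
    all_exclusive: list[str]
    exclusive: list[str]
    non_exclusive: list[str]
    classifications: list[TreeClassification]
    actions: list[tuple[Path, Path]]
    skipped: list[tuple[str, str]]  # (filename, reason)
    log_path: Path


def _scan(job: SortJob) -> list[Path]:
    if not job.in_dir.is_dir():
        raise SortJobError(f"input directory does not exist: {job.in_dir}")
    files = sorted(
        p
        for p in job.in_dir.iterdir()
        if p.is_file() and p.name.endswith(job.extension)
    )
    if not files:
        raise SortJobError(
            f"no files with extension {job.extension!r} in {job.in_dir}"
        )
    return files


def write_log(
    log_path: Path,
    classifications: list[TreeClassification],
    skipped: list[tuple[str, str]],
) -> Path:
    """Tab-separated record per qualifying clade, one header row.

    Rows are ordered by filename, then clade size (largest first), then
    leaf names, so reruns of identical inputs are byte-identical.
    Unparseable inputs appear as SKIPPED rows.
    """
    rows = []
    for cls in classifications:
        name = cls.source_file.name if cls.source_file else "-"
        for clade, tag in cls.qualifying_clades:
            rows.append(
                (
                    name,
                    tag,
                    format_number(clade.support),
                    str(clade.n_target),
                    str(clade.n_nontarget),
                    f"{clade.prop_within:.6g}",
                    f"{clade.prop_of_tree_targets:.6g}",
                    ";".join(clade.leaf_labels),
                )
            )
    for name, reason in skipped:
        rows.append((name, "SKIPPED", "NA", "NA", "NA", "NA", "NA", reason))
    rows.sort(key=lambda r: r[0])
    with open(log_path, "w") as fh:
        fh.write("\t".join(_LOG_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return log_path


def _destination(job: SortJob, cls: TreeClassification) -> Optional[Path]:
    base = job.in_dir / job.out_dir
    if EXCLUSIVE in cls.labels:
        if ALL_EXCLUSIVE in cls.labels:
            return base / "Exclusive" / "All_Exclusive"
        return base / "Exclusive"
    if NON_EXCLUSIVE in cls.labels:
        return base / "Non_Exclusive"
    return None


def sort_trees(job: SortJob) -> SortReport:
    """Classify every matching file in ``job.in_dir`` and act per mode.

    The per-category lists in the returned report are identical across
    modes; only the filesystem side effects differ.  Unparseable files
    are logged as skipped and the run continues.
    """
    files = _scan(job)
    classifications: list[TreeClassification] = []
    skipped: list[tuple[str, str]] = []

    for path in files:
        try:
            tree = parse_tree(path.read_text())
        except NewickParseError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append((path.name, str(exc)))
            continue
        classifications.append(
            classify_tree(tree, job.targets, job.criteria, source_file=path)
        )

    all_exclusive = [
        c.source_file.name for c in classifications if ALL_EXCLUSIVE in c.labels
    ]
    exclusive = [
        c.source_file.name for c in classifications if EXCLUSIVE in c.labels
    ]
    non_exclusive = [
        c.source_file.name for c in classifications if NON_EXCLUSIVE in c.labels
    ]

    actions: list[tuple[Path, Path]] = []
    if job.mode in (MODE_MOVE, MODE_COPY):
        base = job.in_dir / job.out_dir
        if FAMILY_EXCLUSIVE in job.criteria.clades_sorted:
            (base / "Exclusive" / "All_Exclusive").mkdir(parents=True, exist_ok=True)
        if FAMILY_NON_EXCLUSIVE in job.criteria.clades_sorted:
            (base / "Non_Exclusive").mkdir(parents=True, exist_ok=True)
        for cls in classifications:
            dest_dir = _destination(job, cls)
            if dest_dir is None:
                continue
            dest = dest_dir / cls.source_file.name
            if job.mode == MODE_MOVE:
                # copy mode overwrites (re-runs are idempotent); a move
                # onto an existing file would lose data, so it is fatal
                if dest.exists():
                    raise SortJobError(f"destination already exists: {dest}")
                shutil.move(str(cls.source_file), str(dest))
            else:
                shutil.copy(str(cls.source_file), str(dest))
            actions.append((cls.source_file, dest))

    log_path = write_log(
        job.in_dir / f"{job.out_dir}.log", classifications, skipped
    )
    logger.info(
        "sorted %d files: %d exclusive (%d all-exclusive), %d non-exclusive, %d skipped",
        len(files),
        len(exclusive),
        len(all_exclusive),
        len(non_exclusive),
        len(skipped),
    )
    return SortReport(
        all_exclusive=all_exclusive,
        exclusive=exclusive,
        non_exclusive=non_exclusive,
        classifications=classifications,
        actions=actions,
        skipped=skipped,
        log_path=log_path,
    )
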