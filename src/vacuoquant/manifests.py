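"""Manifest and report readers/writers with schema validation.

A dataset manifest is a CSV with columns smear_id, cell_id, file, label,
vacuole_count; ``file`` paths are relative to the manifest's directory.
Malformed rows are reported with their line numbers so problems in hand-built
manifests are easy to locate.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ManifestError, ParameterError
from .pipeline import VacuolizationResult
from .synthetic import LABEL_HEALTHY, LABEL_VACUOLATED

__all__ = ["read_manifest", "write_report", "read_report"]

MANIFEST_COLUMNS = ("smear_id", "cell_id", "file", "label", "vacuole_count")


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Read and validate a dataset manifest CSV.

    Raises :class:`ManifestError` naming the offending rows (1-based data
    line numbers) for unknown labels or missing image files.
    """
    path = Path(path)
    try:
        manifest = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise ManifestError(f"manifest {path} lacks columns {missing_cols}")
    if manifest.empty:
        raise ParameterError(f"manifest {path} contains no rows")

    bad_labels = manifest[~manifest["label"].isin([LABEL_VACUOLATED, LABEL_HEALTHY])]
    if not bad_labels.empty:
        rows = [int(i) + 2 for i in bad_labels.index[:10]]  # +2: header + 1-based
        raise ManifestError(f"unknown labels at manifest lines {rows}")
    if check_files:
        root = path.parent
        missing = [
            (int(i) + 2, f)
            for i, f in manifest["file"].items()
            if not (root / f).is_file()
        ]
        if missing:
            shown = ", ".join(f"line {ln}: {f}" for ln, f in missing[:10])
            raise ManifestError(f"manifest references missing images ({shown})")
    return manifest


def write_report(results: list[VacuolizationResult], path: str | Path) -> None:
    """Persist per-smear results as JSON (with per-cell calls) and CSVs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [r.to_dict() for r in results]
    path.write_text(json.dumps(payload, indent=2))

    smear_rows = [
        {
            "smear_id": r.smear_id,
            "n_total": r.n_cells_total,
            "n_excluded": r.n_cells_excluded,
            "n_vacuolated": r.n_vacuolated,
            "percent": r.percent_vacuolated,
        }
        for r in results
    ]
    pd.DataFrame(smear_rows).to_csv(path.with_suffix(".smears.csv"), index=False)
    cell_rows = [
        {
            "smear_id": r.smear_id,
            "cell_id": c.cell_id,
            "p_vacuolated": c.p_vacuolated,
            "decision": c.decision,
            "excluded": c.excluded,
        }
        for r in results
        for c in r.per_cell
    ]
    pd.DataFrame(cell_rows).to_csv(path.with_suffix(".cells.csv"), index=False)


def read_report(path: str | Path) -> list[VacuolizationResult]:
    payload = json.loads(Path(path).read_text())
    return [VacuolizationResult.from_dict(d) for d in payload]
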