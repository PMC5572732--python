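"""CSV readers/writers with schema versioning and validation.

Every table this package writes starts with comment lines carrying the
schema version and provenance (config hash, seed, package version); readers
skip comments, validate the column set and the row-level invariants, and
refuse files written by a future schema so silent format drift cannot
corrupt an analysis.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = [
    "SCHEMA_VERSION",
    "read_sessions",
    "write_sessions",
    "read_table",
    "write_table",
]

SCHEMA_VERSION = 1

SESSION_COLUMNS = [
    "rat_id", "phase", "session_index", "period",
    "active_presses", "inactive_presses", "rewards", "shocks",
]
PHASES = {
    "saccharine_training", "ethanol_training", "nodrug_test",
    "pr_test", "punishment_test", "choice_test",
}
PERIODS = {"available", "unavailable", "whole"}


def _header_lines(provenance: dict | None) -> list[str]:
    lines = [f"# threecrit-schema: {SCHEMA_VERSION}", f"# threecrit-version: {__version__}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a tidy table as UTF-8, LF-terminated CSV with a schema header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _header_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path, required_columns=None) -> pd.DataFrame:
    """Read a schema-versioned CSV, refusing future schema versions."""
    path = Path(path)
    version = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# threecrit-schema:"):
                version = int(line.split(":", 1)[1])
    if version is not None and version > SCHEMA_VERSION:
        raise ValueError(
            f"{path.name} was written with schema version {version}; this build "
            f"reads versions up to {SCHEMA_VERSION} -- upgrade the package"
        )
    df = pd.read_csv(path, comment="#")
    if required_columns is not None:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise ValueError(f"{path.name} lacks required columns: {sorted(missing)}")
        unknown = set(df.columns) - set(required_columns)
        if unknown:
            raise ValueError(f"{path.name} has unknown columns: {sorted(unknown)}")
    if df.empty:
        warnings.warn(f"{path.name} contains a header but no rows", stacklevel=2)
    return df


def validate_sessions(df: pd.DataFrame) -> None:
    """Row-level invariants of a session table; errors cite row numbers."""
    problems = []
    counts = ["active_presses", "inactive_presses", "rewards", "shocks"]
    neg = df.index[(df[counts] < 0).any(axis=1)]
    problems += [f"row {i}: negative count" for i in neg[:5]]
    over = df.index[df["rewards"] > df["active_presses"]]
    problems += [f"row {i}: rewards > active_presses" for i in over[:5]]
    bad_phase = df.index[~df["phase"].isin(PHASES)]
    problems += [f"row {i}: unknown phase '{df.loc[i, 'phase']}'" for i in bad_phase[:5]]
    bad_period = df.index[~df["period"].isin(PERIODS)]
    problems += [f"row {i}: unknown period '{df.loc[i, 'period']}'" for i in bad_period[:5]]
    shocked = df.index[(df["shocks"] > 0) & (df["phase"] != "punishment_test")]
    problems += [f"row {i}: shocks outside punishment_test" for i in shocked[:5]]
    unavail = df.index[(df["phase"] == "nodrug_test") & (df["period"] == "unavailable")
                       & (df["rewards"] != 0)]
    problems += [f"row {i}: rewards in an unavailable period" for i in unavail[:5]]
    if problems:
        raise ValueError("invalid session rows: " + "; ".join(problems))


def write_sessions(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    validate_sessions(df)
    write_table(df[SESSION_COLUMNS], path, provenance)


def read_sessions(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required_columns=SESSION_COLUMNS)
    if not df.empty:
        validate_sessions(df)
    return df
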