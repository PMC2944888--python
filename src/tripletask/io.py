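"""Tab-separated readers/writers with provenance headers.

Every output table starts with comment lines carrying the config hash and
the master seed, so any file can be traced back to the run that produced
it.  Events files use 0-based millisecond onsets from trial start; scan
indices are 0-based.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .engine import DemandTrace

__all__ = ["write_table", "read_table", "trace_events_frame"]


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> Path:
    """Write a DataFrame as TSV with ``# key=value`` provenance headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def trace_events_frame(trace: DemandTrace, trial_id: object) -> pd.DataFrame:
    """Demand trace as an events table (one row per module action):
    trial_id, resource, onset_ms, duration_ms, tag."""
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "resource": [e.resource for e in trace.events],
            "onset_ms": [e.start_ms for e in trace.events],
            "duration_ms": [e.end_ms - e.start_ms for e in trace.events],
            "tag": [e.tag for e in trace.events],
        }
    )
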