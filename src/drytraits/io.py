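"""CSV and Newick dialects used by the pipeline.

Trait CSV: row 1 repeats the trait name over its modality columns, row 2
gives the modality labels, column 1 holds taxon labels; cells are raw
integer scores or normalized reals (auto-detected — any block not summing
to 1 triggers normalization, which is idempotent either way).
Community CSV: long format (river, site, date, taxon, abundance).
FI CSV: (river, site, fi) with FI in % of the year without flow.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .community import CommunityData, FI_COLUMNS, RECORD_COLUMNS
from .scheme import TraitScheme
from .traits import TraitDatabase, normalize_fuzzy


def write_trait_csv(trait_db: TraitDatabase, path: str | Path) -> None:
    trait_db.affinity.to_csv(path)


def read_trait_csv(path: str | Path, scheme: TraitScheme | None = None) -> TraitDatabase:
    """Read a two-row-header trait table; normalize blocks as needed.

    When no scheme is supplied it is rebuilt from the header (without
    resistance flags, which are generator metadata, not table content).
    """
    frame = pd.read_csv(path, header=[0, 1], index_col=0)
    frame.index = frame.index.astype(str)
    if scheme is None:
        traits: dict[str, list[str]] = {}
        for trait, modality in frame.columns:
            traits.setdefault(str(trait), []).append(str(modality))
        scheme = TraitScheme(
            traits=tuple(traits),
            modalities={k: tuple(v) for k, v in traits.items()},
        )
    expected = scheme.columns
    got = [(str(a), str(b)) for a, b in frame.columns]
    if got != expected:
        raise ValueError(
            "trait CSV columns do not match the scheme "
            f"(first mismatch at {next((i for i, (x, y) in enumerate(zip(got, expected)) if x != y), len(got))})"
        )
    return normalize_fuzzy(frame, scheme)


def write_community_csv(community: CommunityData, records_path: str | Path,
                        fi_path: str | Path,
                        truth_path: str | Path | None = None) -> None:
    community.records.to_csv(records_path, index=False)
    community.fi.to_csv(fi_path, index=False)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(community.truth, indent=2))


def read_community_csv(records_path: str | Path, fi_path: str | Path,
                       truth_path: str | Path | None = None) -> CommunityData:
    records = pd.read_csv(records_path, dtype={"river": str, "site": str,
                                               "date": str, "taxon": str})
    fi = pd.read_csv(fi_path, dtype={"river": str, "site": str})
    truth = {}
    if truth_path is not None and Path(truth_path).exists():
        truth = json.loads(Path(truth_path).read_text())
    return CommunityData(records=records[RECORD_COLUMNS], fi=fi[FI_COLUMNS], truth=truth)


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
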