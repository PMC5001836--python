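"""Table I/O with provenance headers.

Every CSV/TSV the pipeline writes starts with '#'-prefixed comment lines
recording the package version, config hash, and seed; readers skip them, so
round-tripping any schema is lossless.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_table", "read_table"]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
    sep: str = ",",
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# screenpolish v{__version__}"]
    if config_hash is not None:
        header.append(f"# config_sha256={config_hash}")
    if seed is not None:
        header.append(f"# seed={seed}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, sep=sep)
    return path


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")
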