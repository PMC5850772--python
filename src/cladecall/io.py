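"""Plain-TSV input/output with `#`-comment headers.

Every table the pipeline writes starts with comment lines recording the
package version, the random seed and the configuration hash, so any
intermediate file is self-describing and the pipeline can be restarted
from it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from cladecall import __version__
from cladecall.qpcr import ExpressionMatrix


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cladecall {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_matrix(
    matrix: ExpressionMatrix,
    prefix: str | Path,
    meta: Mapping[str, object] | None = None,
) -> tuple[Path, Path]:
    """Write an expression matrix as `<prefix>.tsv` plus `<prefix>.se.tsv`."""
    prefix = Path(prefix)
    main = prefix.with_suffix(".tsv")
    se = prefix.with_suffix(".se.tsv")
    write_table(matrix.log2, main, meta, index=True)
    write_table(matrix.se, se, meta, index=True)
    return main, se


def read_matrix(prefix: str | Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    log2 = read_table(prefix.with_suffix(".tsv"), index_col=0)
    log2.index = log2.index.astype(str)
    se_path = prefix.with_suffix(".se.tsv")
    if se_path.exists():
        se = read_table(se_path, index_col=0)
        se.index = se.index.astype(str)
    else:
        se = log2 * 0.0
    return ExpressionMatrix(log2, se)
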