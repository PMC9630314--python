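"""Readers/writers for the small text formats the pipeline exchanges.

GMT gene-set files (one set per line: name, description, members), the
two-column ``.rnk`` convention for ranked profiles, and plain TSV for
signatures and embeddings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes]}``.

    The second tab field (description/URL) is discarded; duplicate set
    names raise.
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs name, description, >=1 gene): {line!r}")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        if not genes:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    """Read a two-column gene/score file into a descending-sorted Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    s = pd.Series(df["score"].to_numpy(float), index=df["gene"].astype(str))
    return s.sort_values(ascending=False, kind="stable")


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", header=False)
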