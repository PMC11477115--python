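"""Heterologous-host codon-frequency comparison and RSCU clustering.

Host comparison works on per-thousand codon frequencies over all 64
codons: a species/host frequency ratio within (0.5, 2) is a negligible
difference; ratios <= 0.5 or >= 2 mark the codon divergent.  Species
clustering uses squared Euclidean distances between species' 59-codon RSCU
profiles under between-groups average linkage (the "intergroup linkage"
of SPSS-style packages), serialised as newick.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .composition import CodonCountTable
from .genetics import CODONS

HOST_NAMES = ("e_coli", "s_cerevisiae", "n_tabacum", "a_thaliana")


@dataclass
class FrequencyTable:
    """Per-codon frequency per thousand codons; values sum to 1000."""

    source: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.values)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)}")
        total = sum(self.values.values())
        if abs(total - 1000.0) > 1e-6:
            raise ValueError(f"frequencies sum to {total}, expected 1000")


@dataclass
class HostComparison:
    host: str
    ratios: dict[str, float | None]
    divergent: set[str]

    @property
    def n_divergent(self) -> int:
        return len(self.divergent)


@dataclass
class ClusterNode:
    label: str  # lexicographically smallest leaf below this node
    height: float
    leaves: tuple[str, ...]
    children: tuple["ClusterNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    root: ClusterNode
    merges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.root.leaves

    def newick(self) -> str:
        def render(node: ClusterNode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{branch:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{branch:.6g}"

        if self.root.is_leaf:
            return f"{self.root.label};"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def per_thousand_frequency(counts: CodonCountTable, source: str = "") -> FrequencyTable:
    """1000 * count / total for each of the 64 codons."""
    if counts.total_codons == 0:
        raise ValueError("zero total codons")
    values = {
        c: 1000.0 * counts[c] / counts.total_codons for c in CODONS
    }
    return FrequencyTable(source=source, values=values)


def host_divergence(
    species: FrequencyTable, host: FrequencyTable
) -> HostComparison:
    """Per-codon species/host frequency ratios and the divergent set.

    A codon is divergent when ratio <= 0.5 or >= 2 (closed thresholds).
    Host frequency 0 with species > 0 counts divergent with an undefined
    ratio; both 0 is excluded.
    """
    ratios: dict[str, float | None] = {}
    divergent: set[str] = set()
    for codon in CODONS:
        s, h = species.values[codon], host.values[codon]
        if h == 0:
            if s > 0:
                ratios[codon] = None
                divergent.add(codon)
            continue
        ratio = s / h
        ratios[codon] = ratio
        if ratio <= 0.5 or ratio >= 2.0:
            divergent.add(codon)
    return HostComparison(host=host.source, ratios=ratios, divergent=divergent)


def load_host_table(name: str) -> FrequencyTable:
    """Load a packaged host codon-frequency table by short name.

    The shipped tables are synthetic snapshots: approximate per-thousand
    codon frequencies for E. coli, S. cerevisiae, N. tabacum and
    A. thaliana, renormalised to sum exactly 1000.
    """
    if name not in HOST_NAMES:
        raise ValueError(f"unknown host {name!r}; choose from {HOST_NAMES}")
    resource = importlib.resources.files("cubkit.data.hosts") / f"{name}.synthetic.tsv"
    return read_frequency_table(resource, source=name)


def read_frequency_table(path, source: str | None = None) -> FrequencyTable:
    """Read a codon<TAB>per-thousand table, renormalising to sum 1000."""
    values: dict[str, float] = {}
    text = Path(str(path)).read_text() if not hasattr(path, "read_text") else path.read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("codon"):
            continue
        codon, freq = line.split("\t")[:2]
        values[codon.upper().replace("U", "T")] = float(freq)
    total = sum(values.values())
    if total <= 0:
        raise ValueError("frequency table is empty")
    values = {c: 1000.0 * v / total for c, v in values.items()}
    for c in CODONS:
        values.setdefault(c, 0.0)
    return FrequencyTable(source=source or str(path), values=values)


def rscu_cluster(matrix: pd.DataFrame) -> ClusterTree:
    """Cluster species by RSCU with average linkage on squared distances.

    ``matrix`` is species x codon; NaN entries are imputed as 0.  The
    dissimilarity is the squared Euclidean distance; merging follows
    between-groups average linkage with ties broken by the lexicographic
    pair of cluster labels (a cluster's label is its smallest leaf).
    """
    labels = list(matrix.index)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate species labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 species")
    x = matrix.fillna(0.0).to_numpy(dtype=float)
    nodes = {
        lab: ClusterNode(label=lab, height=0.0, leaves=(lab,))
        for lab in labels
    }
    sizes = {lab: 1 for lab in labels}
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = float(np.sum((x[labels.index(a)] - x[labels.index(b)]) ** 2))
            dist[frozenset((a, b))] = d

    merges: list[tuple[str, str, float]] = []
    active = list(labels)
    while len(active) > 1:
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                lo, hi = sorted((a, b))
                key = (dist[frozenset((a, b))], lo, hi)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merged_label = min(a, b)
        child_a, child_b = nodes[a], nodes[b]
        new_node = ClusterNode(
            label=merged_label,
            height=d,
            leaves=tuple(sorted(child_a.leaves + child_b.leaves)),
            children=(child_a, child_b),
        )
        merges.append((a, b, d))
        # Lance-Williams update for average linkage
        for other in active:
            if other in (a, b):
                continue
            da = dist[frozenset((a, other))]
            db = dist[frozenset((b, other))]
            new_d = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            dist[frozenset((merged_label, other))] = new_d
        active = [lab for lab in active if lab not in (a, b)] + [merged_label]
        sizes[merged_label] = sizes[a] + sizes[b]
        nodes[merged_label] = new_node
    return ClusterTree(root=nodes[active[0]], merges=merges)
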