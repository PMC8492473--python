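"""TE and gene annotations.

TE copies carry the RepeatMasker-style hierarchy class -> superfamily ->
family; the family label is serialized as "name:superfamily:class"
(e.g. MMVL30-int:ERV1:LTR).  Genes carry an interval and a TSS which is
the 5' end of the gene under the half-open convention: start for +
strand, end - 1 for - strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval


@dataclass(frozen=True)
class TECopy:
    copy_id: str
    family: str
    superfamily: str
    te_class: str
    interval: GenomicInterval

    @property
    def label(self) -> str:
        return f"{self.family}:{self.superfamily}:{self.te_class}"


def parse_family_label(label: str) -> tuple[str, str, str]:
    parts = label.split(":")
    if len(parts) != 3 or not all(parts):
        raise ValueError(f"family label {label!r} is not name:superfamily:class")
    return parts[0], parts[1], parts[2]


@dataclass
class TEAnnotation:
    copies: list[TECopy]

    def __post_init__(self) -> None:
        ids = [c.copy_id for c in self.copies]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate copy_ids")

    @property
    def family_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for c in self.copies:
            idx.setdefault(c.label, []).append(c.copy_id)
        return idx

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.copies:
            seen.setdefault(c.label)
        return list(seen)

    def by_id(self) -> dict[str, TECopy]:
        return {c.copy_id: c for c in self.copies}

    def __len__(self) -> int:
        return len(self.copies)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class GeneAnnotation:
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_ids")

    def by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)
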