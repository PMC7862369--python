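"""Gene signatures and the bundled reference gene sets.

Three fixed gene lists ship with the package: the 10-gene preliminary IFN-g
inflammation signature, the 18-gene immunosuppression signature (IMS) whose
members mark cancer-associated fibroblasts, tumor-associated macrophages and
their cytokines, and the 20 housekeeping genes used for per-sample
self-normalization of log2 FPKM data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

#: 10-gene "preliminary" IFN-g signature (inflamed microenvironment).
IFNG_10 = (
    "IFNG", "STAT1", "CCR5", "CXCL9", "CXCL10",
    "CXCL11", "IDO1", "PRF1", "GZMA", "HLA-DRA",
)

#: 18-gene immunosuppression signature (CAF/TAM markers and their cytokines).
IMS_18 = (
    "FAP", "PDGFRB", "CD163", "SIGLEC1", "IL10", "CCL2", "CCL8", "CCL13",
    "INHBA", "VCAN", "AXL", "TWIST2", "ADAM12", "COL6A3", "STC1", "ISG15",
    "BCAT1", "OLFML2B",
)

#: 20 low-variance reference ("housekeeping") genes.
HK_20 = (
    "ABCF1", "DNAJC14", "ERCC3", "G6PD", "GUSB", "MRPL19", "NRDE2", "OAZ1",
    "POLR2A", "PSMC4", "PUM1", "SDHA", "SF3A1", "STK11IP", "TBC1D10B", "TBP",
    "TFRC", "TLK2", "TMUB2", "UBB",
)

SCORING_METHODS = ("mean", "pc1", "pair_sum")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene list with its scoring method.

    method "mean": arithmetic mean of the member genes' (log2) expression.
    method "pc1": per-sample projection on the first principal component of
    the member-gene submatrix, sign-oriented to correlate positively with
    the member-gene mean.
    method "pair_sum": count of ordered pairs (a, b) with expr(a) > expr(b);
    requires ``pairs``.
    """

    name: str
    genes: tuple[str, ...]
    method: str = "mean"
    pairs: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self):
        if self.method not in SCORING_METHODS:
            raise ValueError(f"unknown scoring method {self.method!r}")
        genes = tuple(str(g).upper() for g in self.genes)
        if not genes:
            raise ValueError(f"signature {self.name!r}: gene list is empty")
        object.__setattr__(self, "genes", genes)
        pairs = tuple((str(a).upper(), str(b).upper()) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if self.method == "pair_sum":
            if not pairs:
                raise ValueError(f"signature {self.name!r}: method pair_sum requires pairs")
            universe = set(genes)
            for a, b in pairs:
                if a not in universe or b not in universe:
                    raise ValueError(
                        f"signature {self.name!r}: pair ({a}, {b}) references "
                        f"genes outside the signature gene list"
                    )


def builtin_gene_sets() -> list[GeneSignature]:
    """The three bundled fixtures as mean-method signatures."""
    return [
        GeneSignature("IFNG_10", IFNG_10, "mean"),
        GeneSignature("IMS_18", IMS_18, "mean"),
        GeneSignature("HK_20", HK_20, "mean"),
    ]


def load_gene_sets(path: str) -> list[GeneSignature]:
    """Load signatures from a JSON array, or the fixtures for ``"builtin"``.

    Each entry is ``{"name": ..., "genes": [...], "method": "mean"|"pc1"|
    "pair_sum", "pairs": [[a, b], ...]?}``.
    """
    if path == "builtin":
        return builtin_gene_sets()
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError("gene-set JSON must be an array of signature objects")
    sigs = []
    for entry in raw:
        sigs.append(GeneSignature(
            name=entry["name"],
            genes=tuple(entry["genes"]),
            method=entry.get("method", "mean"),
            pairs=tuple(tuple(p) for p in entry.get("pairs", [])),
        ))
    return sigs
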