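"""Core domain containers: expression matrices, clinical tables, cohorts.

Expression values live in a genes x samples :class:`pandas.DataFrame`; the
container adds a ``scale_tag`` recording where the matrix sits in the
log2 -> housekeeping-normalized -> IFN-g-adjusted pipeline so that stages
cannot be applied twice or out of order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("imsig")

#: Valid positions in the normalization pipeline.
SCALE_TAGS = ("linear_fpkm", "log2", "log2_hknorm", "log2_hknorm_ifngadj")

#: RECIST best-overall-response categories.
RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")


class ExpressionMatrix:
    """Genes x samples expression grid with a normalization-state tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric grid, index = gene symbols, columns = sample ids.
    scale_tag : str
        One of :data:`SCALE_TAGS`. ``linear_fpkm`` requires all values >= 0.
    """

    def __init__(self, values: pd.DataFrame, scale_tag: str = "linear_fpkm"):
        if scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {scale_tag!r}; expected one of {SCALE_TAGS}")
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        if values.size == 0:
            raise ValueError("expression matrix is empty")
        values = values.copy()
        values.index = [str(g).upper() for g in values.index]
        values.columns = [str(s) for s in values.columns]
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            bad = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}; imputation is refused"
            )
        if scale_tag == "linear_fpkm" and (arr < 0).any():
            raise ValueError("linear_fpkm matrix contains negative values")
        self.values = values.astype(float)
        self.scale_tag = scale_tag

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.scale_tag)

    def with_values(self, values: pd.DataFrame, scale_tag: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, scale_tag)

    def present_genes(self, genes, context: str = "gene set") -> list[str]:
        """Intersect ``genes`` with the matrix, warning about absentees."""
        idx = set(self.values.index)
        present = [g.upper() for g in genes if g.upper() in idx]
        missing = [g.upper() for g in genes if g.upper() not in idx]
        if missing:
            logger.warning("%s: %d gene(s) absent from matrix, excluded: %s",
                           context, len(missing), ", ".join(sorted(missing)))
        return present

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, scale={self.scale_tag})"


class ClinicalTable:
    """Per-sample clinical annotations: RECIST response and optional survival.

    Stored as a DataFrame indexed by sample id with columns ``response``
    (CR/PR/SD/PD), optional ``os_time`` (months) and ``os_event``
    (1 = death, 0 = censored), and optional ``cohort`` label.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "sample_id" in table.columns:
            table = table.set_index("sample_id")
        table.index = [str(s) for s in table.index]
        if pd.Index(table.index).has_duplicates:
            dups = pd.Index(table.index)
            raise ValueError(f"duplicate sample ids: {dups[dups.duplicated()].unique().tolist()}")
        if "response" not in table.columns:
            raise ValueError("clinical table requires a 'response' column")
        resp = table["response"].astype(str).str.strip().str.upper()
        bad = sorted(set(resp) - set(RESPONSE_CATEGORIES))
        if bad:
            raise ValueError(f"unknown response value(s): {bad}; expected {RESPONSE_CATEGORIES}")
        table["response"] = resp
        has_time = "os_time" in table.columns
        has_event = "os_event" in table.columns
        if has_time != has_event:
            raise ValueError("os_time and os_event must be provided together")
        if has_time:
            table["os_time"] = table["os_time"].astype(float)
            if (table["os_time"] < 0).any():
                raise ValueError("os_time must be >= 0")
            ev = table["os_event"].astype(int)
            if not ev.isin([0, 1]).all():
                raise ValueError("os_event must be 0 (censored) or 1 (death)")
            table["os_event"] = ev
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def response(self) -> pd.Series:
        return self.table["response"]

    @property
    def has_survival(self) -> bool:
        return "os_time" in self.table.columns

    def responders(self, definition: str = "crpr") -> pd.Series:
        """Boolean actual-responder labels under either dichotomy.

        ``crpr``: CR/PR = responder, PD = nonresponder, SD excluded (NaN-free:
        SD rows are dropped). ``disease_control``: CR/PR/SD = responder.
        """
        if definition == "crpr":
            sub = self.table[self.table["response"] != "SD"]
            return sub["response"].isin(["CR", "PR"])
        if definition == "disease_control":
            return self.table["response"].isin(["CR", "PR", "SD"])
        raise ValueError(f"unknown responder definition {definition!r}")

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)])

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ClinicalTable({len(self)} samples, survival={self.has_survival})"


@dataclass
class Cohort:
    """A named expression matrix paired with clinical annotations.

    Clinical sample ids must be a subset of expression sample ids; expression
    samples without clinical rows are kept in ``expression`` but ignored by
    response-based stages.  Clinical rows without expression are an error.
    """

    name: str
    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self):
        expr_samples = set(self.expression.sample_ids)
        clin_samples = self.clinical.sample_ids
        missing = [s for s in clin_samples if s not in expr_samples]
        if missing:
            raise ValueError(
                f"cohort {self.name!r}: clinical samples absent from expression: {missing}"
            )
        extra = [s for s in self.expression.sample_ids if s not in set(clin_samples)]
        if extra:
            logger.warning("cohort %s: %d expression sample(s) lack clinical rows: %s",
                           self.name, len(extra), ", ".join(extra))

    @property
    def n_samples(self) -> int:
        return len(self.clinical)


@dataclass
class SignatureScores:
    """Per-sample scores for one signature (log2 units for mean scores)."""

    signature_name: str
    scores: pd.Series = field(repr=False)

    def __post_init__(self):
        self.scores = self.scores.astype(float)
        self.scores.index = [str(s) for s in self.scores.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)
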