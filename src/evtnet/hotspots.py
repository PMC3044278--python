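"""Relating average signal traffic to alanine-scanning ΔΔG: binding hot-spot regression.

Binding hot spots are interface residues whose mutation to alanine causes a
large change in binding free energy (ΔΔG, kcal/mol).  If hot spots mediate
signal communication between the binding partners, their average EVT traffic
in the complex's structure network should track ΔΔG.  This module fits, per
complex, an ordinary least-squares model of ΔΔG on the (z-scored) traffic of
the mutated wild-type residues.  Complexes with fewer than three mutations
are dropped beforehand: with two points the correlation is always one and the
fit says nothing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .markov import zscore_profile
from .structure_io import StructureModel

__all__ = [
    "MutationRecord",
    "RegressionResult",
    "MIN_MUTATIONS",
    "read_ddg_table",
    "filter_complexes",
    "traffic_map",
    "fit_hotspot_model",
]

logger = logging.getLogger(__name__)

#: minimum alanine mutations per complex for a meaningful regression
MIN_MUTATIONS = 3


@dataclass(frozen=True)
class MutationRecord:
    """One alanine-scanning measurement: residue identity and its ΔΔG in kcal/mol."""

    complex_id: str
    chain: str
    resnum: int
    ddg: float
    icode: str = ""

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


@dataclass
class RegressionResult:
    """Per-complex OLS fit of ΔΔG on average EVT traffic.

    ``pearson_r`` is the correlation between fitted and observed ΔΔG (equal
    to |r(traffic, ΔΔG)| for a single predictor); ``residual_se`` the
    residual standard error with n-2 degrees of freedom; ``f_pvalue`` the
    p-value of the overall F test.
    """

    complex_id: str
    n_mutations: int
    slope: float
    intercept: float
    pearson_r: float
    residual_se: float
    f_pvalue: float
    fitted: np.ndarray | None = None
    observed: np.ndarray | None = None


def read_ddg_table(source) -> list[MutationRecord]:
    """Read a ΔΔG table (TSV with header) into mutation records.

    Required columns: ``complex_id``, ``chain``, ``resnum``, ``ddg_kcal_mol``
    (or ``ddg``); optional: ``icode``, ``pdb_id`` (carried through complex_id
    grouping only).  Duplicate (complex, chain, resnum, icode) entries are an
    error.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype={"chain": str})
    ddg_col = "ddg_kcal_mol" if "ddg_kcal_mol" in df.columns else "ddg"
    required = {"complex_id", "chain", "resnum", ddg_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddg table missing columns: {sorted(missing)}")
    if "icode" not in df.columns:
        df["icode"] = ""
    df["icode"] = df["icode"].fillna("").astype(str).str.strip()
    records = [
        MutationRecord(
            complex_id=str(r.complex_id),
            chain=str(r.chain),
            resnum=int(r.resnum),
            icode=str(r.icode),
            ddg=float(getattr(r, ddg_col)),
        )
        for r in df.itertuples()
    ]
    keys = [(m.complex_id, m.chain, m.resnum, m.icode) for m in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate mutation entries: {dupes}")
    if any(not np.isfinite(m.ddg) for m in records):
        raise ValueError("non-finite ddg values in table")
    return records


def filter_complexes(
    records: Sequence[MutationRecord], min_mutations: int = MIN_MUTATIONS
) -> dict[str, list[MutationRecord]]:
    """Group records by complex and drop complexes with too few mutations."""
    groups: dict[str, list[MutationRecord]] = {}
    for rec in records:
        groups.setdefault(rec.complex_id, []).append(rec)
    kept: dict[str, list[MutationRecord]] = {}
    for cid, recs in groups.items():
        if len(recs) < min_mutations:
            logger.info(
                "dropping complex %s: %d mutation(s) < %d", cid, len(recs), min_mutations
            )
            continue
        kept[cid] = recs
    return kept


def traffic_map(model: StructureModel, traffic: np.ndarray) -> dict[tuple[str, int, str], float]:
    """Map (chain, resnum, icode) -> traffic value for residue lookup."""
    traffic = np.asarray(traffic, dtype=float)
    if traffic.shape != (len(model.nodes),):
        raise ValueError("traffic vector length must equal node count")
    return {
        (n.node_id.chain, n.node_id.resnum, n.node_id.icode): float(v)
        for n, v in zip(model.nodes, traffic)
    }


def fit_hotspot_model(
    traffic: Mapping[tuple[str, int, str], float],
    records: Sequence[MutationRecord],
    zscore: bool = True,
) -> RegressionResult:
    """OLS of ΔΔG on the average EVT traffic of one complex's mutated residues.

    ``traffic`` maps residue keys (chain, resnum, icode) to the structure's
    average-EVT values; by default the whole traffic profile is z-scored
    before the mutated residues are looked up.  Every record must map onto a
    node exactly (chain + residue number + insertion code).
    """
    records = list(records)
    if len(records) < MIN_MUTATIONS:
        raise ValueError(
            f"need at least {MIN_MUTATIONS} mutations, got {len(records)}"
        )
    complex_ids = {r.complex_id for r in records}
    if len(complex_ids) != 1:
        raise ValueError(f"records span multiple complexes: {sorted(complex_ids)}")
    values = dict(traffic)
    if zscore:
        keys = list(values)
        zvals = zscore_profile(np.array([values[k] for k in keys]))
        values = dict(zip(keys, zvals))
    missing = [r for r in records if r.residue_key() not in values]
    if missing:
        raise KeyError(
            "mutated residues not found in structure: "
            + ", ".join(f"{m.chain}:{m.resnum}{m.icode}" for m in missing)
        )
    x = np.array([values[r.residue_key()] for r in records])
    y = np.array([r.ddg for r in records])
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance across the mutated residues")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    fitted = fit.fittedvalues
    if np.std(fitted) == 0:  # slope exactly 0: correlation undefined, report 0
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    return RegressionResult(
        complex_id=records[0].complex_id,
        n_mutations=len(records),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pearson_r=r,
        residual_se=float(np.sqrt(fit.scale)),
        f_pvalue=float(fit.f_pvalue),
        fitted=np.asarray(fitted),
        observed=y,
    )
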