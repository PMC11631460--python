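"""Rolling probe p-values up to epitopes and epitopes up to proteins.

Raw (not adjusted) p-values feed each roll-up: probe combined p-values are
combined into an epitope p-value per positive sample, epitope raw p-values
into a protein p-value.  Benjamini-Hochberg is applied once per level,
within each positive-sample column, followed by FDR thresholding and
K-of-N summaries.  Combining already-adjusted p-values would correct twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import segmentation
from .calling import k_of_n, make_calls, one_hit_filter
from .metap import MetaMethod
from .probe_stats import adjust_bh, probe_pvalue_layers
from .types import (
    CallMatrix,
    Epitope,
    LevelResults,
    ProbeDataset,
    PValueTable,
    SegmentationConfig,
    StatParams,
    k_of_n_from_calls,
)


def _level_results(
    level: str,
    raw: pd.DataFrame,
    cutoff: float,
    feature_meta: pd.DataFrame | None = None,
) -> LevelResults:
    raw_table = PValueTable("combined", raw)
    adjusted = adjust_bh(raw_table)
    calls = make_calls(adjusted, cutoff, level)
    return LevelResults(
        level=level,
        raw=raw,
        adjusted=adjusted.values,
        calls=calls,
        k_of_n=k_of_n_from_calls(calls.calls),
        feature_meta=feature_meta,
    )


def epitope_pvalues(
    probe_p: PValueTable,
    epitopes: list[Epitope],
    method: MetaMethod,
    cutoff: float,
) -> LevelResults:
    """Combine member-probe raw p-values into per-sample epitope p-values.

    An epitope with no resolvable member probes scores 1.  The combined
    epitope p-values are BH-adjusted per sample across all epitopes, then
    thresholded and summarized as K-of-N.
    """
    samples = list(probe_p.values.columns)
    rows = {}
    meta_rows = []
    for epi in epitopes:
        members = [m for m in epi.member_probes if m in probe_p.values.index]
        if members:
            sub = probe_p.values.loc[members].to_numpy()
            rows[epi.epitope_id] = [method(sub[:, j]) for j in range(sub.shape[1])]
        else:
            rows[epi.epitope_id] = [1.0] * len(samples)
        meta_rows.append(
            (epi.epitope_id, epi.protein_id, epi.first, epi.last, epi.n_probes)
        )
    raw = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    meta = pd.DataFrame(
        meta_rows, columns=["epitope_id", "protein_id", "first", "last", "n_probes"]
    ).set_index("epitope_id")
    return _level_results("epitope", raw, cutoff, meta)


def protein_pvalues(
    epitope_results: LevelResults,
    method: MetaMethod,
    cutoff: float,
) -> LevelResults:
    """Combine each protein's raw epitope p-values into per-sample protein p-values.

    Proteins without any candidate epitope are omitted from the output
    rather than reported at p = 1, so the table size tracks the signal.
    """
    if epitope_results.feature_meta is None:
        raise ValueError("epitope results carry no protein mapping")
    protein_of = epitope_results.feature_meta["protein_id"]
    samples = list(epitope_results.raw.columns)
    rows = {}
    for protein, group in epitope_results.raw.groupby(protein_of, sort=True):
        sub = group.to_numpy()
        rows[protein] = [method(sub[:, j]) for j in range(sub.shape[1])]
    raw = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    n_epitopes = protein_of.groupby(protein_of).size().rename("n_epitopes").to_frame()
    return _level_results("protein", raw, cutoff, n_epitopes.loc[raw.index])


@dataclass
class WorkflowResult:
    """All retained tables from a full run."""

    probe_layers: dict[str, PValueTable]
    probe: LevelResults
    epitopes: list[Epitope]
    epitope: LevelResults
    protein: LevelResults


def run_workflow(
    data: ProbeDataset,
    params: StatParams | None = None,
    seg: SegmentationConfig | None = None,
    epitope_method: MetaMethod | None = None,
    protein_method: MetaMethod | None = None,
) -> WorkflowResult:
    """Full pipeline: probe p-values -> BH -> calls -> one-hit filter ->
    segmentation -> epitope level -> protein level.

    Defaults follow the best-repeatability settings of the method: combined
    global+differential probe p-values, hierarchical/binary segmentation,
    Wilkinson's 2nd max for epitopes and Tippett for proteins, one cutoff
    shared by all three levels.  Deterministic for fixed inputs.
    """
    from .metap import get_method

    params = params or StatParams()
    seg = seg or SegmentationConfig()
    epitope_method = epitope_method or get_method("wmax2")
    protein_method = protein_method or get_method("wmin1")

    layers = probe_pvalue_layers(data, params)
    adjusted = layers["adjusted"]
    calls = make_calls(adjusted, params.p_adj_cutoff, "probe")
    if params.one_hit_filter:
        calls, adjusted = one_hit_filter(calls, adjusted, data)
        layers["adjusted"] = adjusted
    probe_level = LevelResults(
        level="probe",
        raw=layers["combined"].values,
        adjusted=adjusted.values,
        calls=calls,
        k_of_n=k_of_n(calls),
        feature_meta=data.probe_meta.loc[data.probe_ids],
    )
    epitopes = segmentation.segment(calls, data, seg, pvalues=layers["combined"])
    epitope_level = epitope_pvalues(
        layers["combined"], epitopes, epitope_method, params.p_adj_cutoff
    )
    protein_level = protein_pvalues(epitope_level, protein_method, params.p_adj_cutoff)
    return WorkflowResult(
        probe_layers=layers,
        probe=probe_level,
        epitopes=epitopes,
        epitope=epitope_level,
        protein=protein_level,
    )
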