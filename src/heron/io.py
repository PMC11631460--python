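"""TSV readers/writers and the run manifest.

Input is a trio of tab-separated files: the intensity matrix (first column
``probe_id``, one column per sample), a sample sheet (``sample_id``,
``label`` in {negative, positive}) and probe metadata (``probe_id``,
``protein_id``, ``start``, ``tiling``, optional ``sequence``).  All output
tables are TSV with a header row; the manifest is YAML.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .aggregation import WorkflowResult
from .synthetic import SynthTruth
from .types import LevelResults, ProbeDataset

logger = logging.getLogger(__name__)


def read_dataset(matrix_path, samples_path, meta_path) -> ProbeDataset:
    """Read and validate the intensity matrix, sample sheet and probe metadata.

    Duplicate probe rows (replicate array spots mapping to one sequence)
    are collapsed by mean with a warning; probes without metadata raise
    with a listing.
    """
    intensities = pd.read_csv(matrix_path, sep="\t", index_col=0)
    bad = intensities.columns[
        ~intensities.dtypes.apply(lambda t: pd.api.types.is_numeric_dtype(t))
    ]
    if len(bad):
        raise ValueError(f"non-numeric intensity columns: {list(bad)}")
    if intensities.index.duplicated().any():
        n_dup = int(intensities.index.duplicated().sum())
        logger.warning("collapsing %d duplicate probe rows by mean", n_dup)
        intensities = intensities.groupby(level=0, sort=False).mean()

    sheet = pd.read_csv(samples_path, sep="\t")
    if not {"sample_id", "label"} <= set(sheet.columns):
        raise ValueError("sample sheet needs columns sample_id, label")
    labels = sheet.set_index("sample_id")["label"]
    missing = [s for s in intensities.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples absent from the sample sheet: {missing}")

    meta = pd.read_csv(meta_path, sep="\t").set_index("probe_id")
    return ProbeDataset(intensities=intensities, sample_labels=labels, probe_meta=meta)


def write_dataset(data: ProbeDataset, outdir, truth: SynthTruth | None = None) -> None:
    """Write the TSV trio (plus a truth table for synthetic data)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.intensities.rename_axis("probe_id").to_csv(outdir / "intensities.tsv", sep="\t")
    data.sample_labels.rename("label").rename_axis("sample_id").to_csv(
        outdir / "samples.tsv", sep="\t"
    )
    data.probe_meta.rename_axis("probe_id").to_csv(outdir / "probe_meta.tsv", sep="\t")
    if truth is not None:
        rows = [
            {
                "protein_id": p.protein_id,
                "start": p.start,
                "end": p.end,
                "effect": p.effect,
                "carriers": ",".join(p.carriers),
                "first_probe": e.first,
                "last_probe": e.last,
            }
            for p, e in zip(truth.planted, truth.true_epitopes)
        ]
        pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _write_level(level: LevelResults, outdir: Path) -> None:
    name = level.level
    raw = level.raw.add_prefix("raw_p_")
    adjusted = level.adjusted.add_prefix("adj_p_")
    calls = level.calls.calls.astype(int).add_prefix("call_")
    table = pd.concat([raw, adjusted, calls, level.k_of_n_frame()], axis=1)
    if level.feature_meta is not None:
        table = pd.concat([level.feature_meta, table], axis=1)
    table.rename_axis("feature_id").to_csv(outdir / f"{name}_results.tsv", sep="\t")


def write_results(result: WorkflowResult, outdir, manifest: dict | None = None) -> None:
    """Write per-level result tables, the epitope list, and a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for level in (result.probe, result.epitope, result.protein):
        _write_level(level, outdir)
    epi_rows = [
        {
            "epitope_id": e.epitope_id,
            "protein_id": e.protein_id,
            "first": e.first,
            "last": e.last,
            "n_probes": e.n_probes,
            "covered_start": e.covered_interval[0],
            "covered_end": e.covered_interval[1],
        }
        for e in result.epitopes
    ]
    pd.DataFrame(
        epi_rows,
        columns=[
            "epitope_id",
            "protein_id",
            "first",
            "last",
            "n_probes",
            "covered_start",
            "covered_end",
        ],
    ).to_csv(outdir / "epitopes.tsv", sep="\t", index=False)

    info = dict(manifest or {})
    info["counts"] = {
        "probes": int(result.probe.raw.shape[0]),
        "epitopes": int(result.epitope.raw.shape[0]),
        "proteins": int(result.protein.raw.shape[0]),
        "probe_calls": int(result.probe.calls.calls.to_numpy().sum()),
        "epitope_calls": int(result.epitope.calls.calls.to_numpy().sum()),
        "protein_calls": int(result.protein.calls.calls.to_numpy().sum()),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(info, fh, sort_keys=True)


def write_epitope_fasta(result: WorkflowResult, data: ProbeDataset, path) -> None:
    """FASTA of covered epitope sequences (requires probe sequences)."""
    if "sequence" not in data.probe_meta.columns:
        raise ValueError("probe metadata has no sequences")
    with open(path, "w") as fh:
        for e in result.epitopes:
            seqs = data.probe_meta.loc[list(e.member_probes), ["start", "sequence"]]
            seqs = seqs.sort_values("start")
            merged = seqs.iloc[0]["sequence"]
            offset = seqs.iloc[0]["start"]
            for start, seq in seqs.iloc[1:].itertuples(index=False):
                merged += seq[len(merged) - (start - offset):]
            fh.write(f">{e.epitope_id}\n{merged}\n")
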