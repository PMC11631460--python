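import numpy as np
import pandas as pd
import pytest

from heron.types import Epitope, ProbeDataset


def build_dataset(
    intensities: np.ndarray,
    n_negative: int,
    protein_ids=None,
    starts=None,
    tiling: int = 1,
) -> ProbeDataset:
    """Assemble a ProbeDataset from a plain array (first columns = negatives)."""
    intensities = np.asarray(intensities, dtype=float)
    n_probes, n_samples = intensities.shape
    probes = [f"pr{i:03d}" for i in range(n_probes)]
    samples = [f"N{i+1}" for i in range(n_negative)] + [
        f"P{i+1}" for i in range(n_samples - n_negative)
    ]
    labels = pd.Series(
        ["negative"] * n_negative + ["positive"] * (n_samples - n_negative),
        index=samples,
    )
    if protein_ids is None:
        protein_ids = ["PROT1"] * n_probes
    if starts is None:
        pos, counter = [], {}
        for p in protein_ids:
            counter[p] = counter.get(p, 0) + 1
            pos.append(1 + (counter[p] - 1) * tiling)
        starts = pos
    meta = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "start": starts,
            "tiling": tiling,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return ProbeDataset(
        intensities=pd.DataFrame(intensities, index=probes, columns=samples),
        sample_labels=labels,
        probe_meta=meta,
    )


def region_of(m: int, protein: str = "P", tiling: int = 1):
    """A bare m-probe region plus a minimal object carrying its probe metadata."""
    probes = tuple(f"{protein};{i}" for i in range(m))
    starts = np.arange(1, 1 + m * tiling, tiling)
    meta = pd.DataFrame(
        {"protein_id": protein, "start": starts, "tiling": tiling},
        index=pd.Index(probes, name="probe_id"),
    )

    class _Carrier:
        probe_meta = meta

    region = Epitope(protein, int(starts[0]), int(starts[-1]), probes)
    return region, _Carrier()


@pytest.fixture
def dataset_factory():
    return build_dataset


@pytest.fixture
def region_factory():
    return region_of
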