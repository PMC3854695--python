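"""Loader for the bundled reference study fixture.

The fixture is a curated per-sample allele-call matrix for the 18 MEG and
6 PEG candidate genes of the reciprocal Col-0 x Ler hybrid embryo survey,
plus the purity-marker panel, seedling and mutant-cross calls, and the
published concordance categories of the confirmed genes in two external
embryo datasets.  See the TSV set's README for provenance details.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .allele_model import SampleSpec, read_sample_sheet


def fixture_dir() -> Path:
    """Filesystem path of the bundled reference study TSVs."""
    return Path(resources.files("imprintcall") / "data" / "reference_study")


def load_reference_study(base: str | Path | None = None) -> dict:
    """Load the reference study tables.

    Returns a dict with keys: ``samples`` (sample_id -> SampleSpec),
    ``candidates``, ``embryo_calls``, ``wash_calls``, ``mutant_calls``,
    ``seedling_calls``, ``markers``, ``concordance``, ``gamete_presence``
    (pandas DataFrames).  ``base`` overrides the bundled directory, so the
    same loader reads user-supplied studies in the fixture layout.
    """
    base = Path(base) if base is not None else fixture_dir()
    samples: dict[str, SampleSpec] = read_sample_sheet(base / "samples.tsv")

    def tsv(name: str) -> pd.DataFrame:
        return pd.read_csv(base / name, sep="\t", dtype=str)

    markers = tsv("markers.tsv")
    markers["detected"] = markers["detected"].astype(int)
    gametes = tsv("gamete_presence.tsv")
    for col in ("egg_present", "sperm_present"):
        gametes[col] = gametes[col].astype(int).astype(bool)
    return {
        "samples": samples,
        "candidates": tsv("candidates.tsv"),
        "embryo_calls": tsv("embryo_calls.tsv"),
        "wash_calls": tsv("wash_calls.tsv"),
        "mutant_calls": tsv("mutant_calls.tsv"),
        "seedling_calls": tsv("seedling_calls.tsv"),
        "markers": markers,
        "concordance": tsv("concordance_labels.tsv"),
        "gamete_presence": gametes,
    }
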