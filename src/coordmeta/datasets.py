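"""Packaged data: the PSP voxel-based morphometry study table.

The fixture transcribes the demographic, clinical, and imaging
characteristics of the 18 whole-brain VBM studies of progressive
supranuclear palsy (284 patients, 367 healthy controls) that the shipped
example analysis meta-analyses.  Per-study peak-coordinate tables are not
part of the public record for these studies, which is exactly why the
package ships a synthetic-data generator (:mod:`coordmeta.synthetic`).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import List

from .study_io import StudyRecord, load_study_table

__all__ = ["psp_study_table_path", "load_psp_studies"]


def psp_study_table_path() -> Path:
    """Filesystem path of the packaged PSP study table TSV."""
    return Path(resources.files("coordmeta").joinpath("data/psp_vbm_studies.tsv"))


def load_psp_studies() -> List[StudyRecord]:
    """Load the packaged PSP study table (18 studies)."""
    return load_study_table(psp_study_table_path())
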