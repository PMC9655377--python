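"""Published reference results for the 70-genotype soybean screening dataset.

The pipeline was designed around a public screening of 70 Brazilian
commercial soybean genotypes under -0.20 MPa saline (NaCl) and drought
(PEG-6000) stress, whose raw data are deposited at
https://github.com/brunobro/selection-of-soybean-genotypes.  The tables
below freeze the reference rankings published for that dataset so that,
when a copy of the deposited data is available locally, the pipeline's
output can be checked against them (:func:`compare_top`).  Nothing in the
package requires the external dataset; these are optional integration
anchors, not test fixtures.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

#: Ten smallest Control/Saline Manhattan distances (ascending).
TOP10_SALINE_DISTANCE: tuple[tuple[str, float], ...] = (
    ("97R73 RR", 0.3132),
    ("TMG 2165 IPRO", 0.3329),
    ("RK 8317 IPRO", 0.3367),
    ("TMG 2378 IPRO", 0.3482),
    ("98R31 IPRO", 0.3670),
    ("98R35 IPRO", 0.3720),
    ("NS 5151 IPRO", 0.3730),
    ("5G 770 RR", 0.3787),
    ("ST 797 IPRO", 0.3800),
    ("ST 777 IPRO", 0.3926),
)

#: Ten smallest Control/Drought Manhattan distances (ascending).
TOP10_DROUGHT_DISTANCE: tuple[tuple[str, float], ...] = (
    ("AS 3575 IPRO", 0.4034),
    ("BMX Ponta IPRO", 0.4578),
    ("BMX Foco IPRO", 0.5371),
    ("RK 6813 RR", 0.5733),
    ("TMG 716 RR", 0.6079),
    ("5D 6215 IPRO", 0.6550),
    ("FPS solar IPRO", 0.6645),
    ("ST 777 IPRO", 0.6649),
    ("RK 7214 IPRO", 0.6805),
    ("5G 830 RR", 0.7158),
)

#: Ten highest equal-weight TOPSIS scores (descending): genotype,
#: (ds, dd), closeness.
TOP10_TOPSIS: tuple[tuple[str, float, float, float], ...] = (
    ("RK 6813 RR", 0.4461, 0.5733, 0.9380),
    ("ST 777 IPRO", 0.3926, 0.6649, 0.9230),
    ("RK 7214 IPRO", 0.4772, 0.6805, 0.9081),
    ("TMG 2165 IPRO", 0.3329, 0.7385, 0.9073),
    ("5G 830 RR", 0.5298, 0.7158, 0.8911),
    ("98R35 IPRO", 0.3720, 0.8048, 0.8878),
    ("98R31 IPRO", 0.3670, 0.8342, 0.8805),
    ("RK 8317 IPRO", 0.3367, 0.8696, 0.8728),
    ("CG 7464 RR", 0.6055, 0.7714, 0.8650),
    ("LG 60177 IPRO", 0.5593, 0.8136, 0.8637),
)

#: Genotype reported in the top-10 at every swept weight pair.
ALWAYS_SELECTED: str = "ST 777 IPRO"


def topsis_frame() -> pd.DataFrame:
    """The reference top-10 TOPSIS table as a DataFrame."""
    return pd.DataFrame(
        list(TOP10_TOPSIS), columns=["genotype", "ds", "dd", "Ci"]
    ).set_index("genotype")


def distance_frames() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference top-10 distance tables (saline, drought)."""
    saline = pd.DataFrame(list(TOP10_SALINE_DISTANCE), columns=["genotype", "ds"])
    drought = pd.DataFrame(list(TOP10_DROUGHT_DISTANCE), columns=["genotype", "dd"])
    return saline.set_index("genotype"), drought.set_index("genotype")


def compare_top(computed: Sequence[str], reference: Sequence[str] | None = None) -> dict:
    """Overlap between a computed ranking and a published top list.

    Parameters
    ----------
    computed : sequence of genotype labels
        e.g. ``results.top(10)`` from a fit on the deposited dataset.
    reference : sequence, optional
        Published labels to compare against; defaults to the reference
        top-10 TOPSIS selection.

    Returns
    -------
    dict with ``overlap`` (count), ``jaccard``, ``missing`` and ``extra``.
    """
    ref = [g for g, *_ in TOP10_TOPSIS] if reference is None else list(reference)
    comp = list(computed)[: len(ref)]
    inter = set(comp) & set(ref)
    union = set(comp) | set(ref)
    return {
        "overlap": len(inter),
        "jaccard": len(inter) / len(union) if union else 1.0,
        "missing": sorted(set(ref) - inter),
        "extra": sorted(set(comp) - set(ref)),
    }
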