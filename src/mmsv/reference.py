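"""Published headline counts from the CoMMpass newly-diagnosed myeloma cohort.

These are the printed patient counts the downstream prevalence figures are
derived from; the raw patient-level data are controlled-access and are not
shipped. The helpers here exist so that prevalence arithmetic is computed,
not hard-coded, wherever the figures are cited.
"""

from __future__ import annotations

#: Headline counts (newly diagnosed patients, long-insert WGS).
COMMPASS_COUNTS = {
    "patients_wgs": 795,
    "patients_t_igl": 78,            # IgL-translocated
    "patients_t_myc": 182,           # MYC-translocated
    "patients_igl_myc": 32,          # IgL-MYC of the IgL-translocated
    "patients_cna_profiled": 777,    # with high-confidence copy-number calls
    "patients_hyperdiploid": 388,    # of the CNA-profiled
    "t_igl_imid": 51,                # t(IgL) receiving front-line IMiD therapy
    "t_igl_no_imid": 23,
    "non_t_igl_imid": 463,
    "non_t_igl_no_imid": 164,
}


def prevalence_pct(numerator: int, denominator: int) -> float:
    """Prevalence as a percentage of a denominator count."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator
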