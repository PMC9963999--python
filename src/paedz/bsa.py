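"""Body surface area formulas.

Three published estimators are supported so that a coefficient file can
record which one its models were fitted against.  Height in cm, weight in
kg, result in m².
"""

from __future__ import annotations

import numpy as np

BSA_FORMULAS = ("mosteller", "dubois", "haycock")


def compute_bsa(height, weight, formula: str = "mosteller"):
    """Body surface area (m²) from height (cm) and weight (kg).

    Parameters
    ----------
    height, weight : float or array-like
        Stature in cm and body mass in kg; both strictly positive.
    formula : {"mosteller", "dubois", "haycock"}
        mosteller : sqrt(height * weight / 3600)
        dubois    : 0.007184 * height**0.725 * weight**0.425
        haycock   : 0.024265 * height**0.3964 * weight**0.5378

    Returns
    -------
    float or ndarray
    """
    h = np.asarray(height, dtype=float)
    w = np.asarray(weight, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise ValueError("height and weight must be strictly positive")
    if formula == "mosteller":
        out = np.sqrt(h * w / 3600.0)
    elif formula == "dubois":
        out = 0.007184 * h**0.725 * w**0.425
    elif formula == "haycock":
        out = 0.024265 * h**0.3964 * w**0.5378
    else:
        raise ValueError(
            f"unknown BSA formula {formula!r}; choose one of {BSA_FORMULAS}"
        )
    if out.ndim == 0:
        return float(out)
    return out
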