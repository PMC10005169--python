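"""Regenerate the bundled synthetic hemoglobin extinction table.

The table (src/msimon/data/synthetic_hb_extinction.csv) is a synthetic
stand-in for tabulated oxy-/deoxyhemoglobin molar extinction coefficients.
It is built from a small set of Gaussian absorption bands plus smooth
baselines chosen to reproduce the qualitative features of the real curves:

* the Soret band near 414 nm (HbO2) / 430 nm (Hb),
* the HbO2 alpha/beta doublet at 542/577 nm versus the single Hb band at
  555 nm, with isosbestic crossings in between,
* the steep fall-off above 600 nm where Hb remains several-fold more
  absorbing than HbO2, and
* weak, slowly varying extinction towards 1000 nm with a crossing near
  800 nm.

Units are liter mol^-1 cm^-1 on a 1 nm grid from 300 to 1000 nm.  The exact
numbers are synthetic and carry no metrological meaning.
"""

from pathlib import Path

import numpy as np
import pandas as pd


def _g(wl, center, sd, amp):
    return amp * np.exp(-0.5 * ((wl - center) / sd) ** 2)


def build_table() -> pd.DataFrame:
    wl = np.arange(300.0, 1000.0 + 0.5, 1.0)

    hbo2 = (
        _g(wl, 414, 14, 4.8e5)
        + _g(wl, 344, 25, 2.8e4)
        + _g(wl, 460, 35, 2.4e4)
        + _g(wl, 542, 11, 5.0e4)
        + _g(wl, 577, 9, 5.4e4)
        + _g(wl, 925, 90, 1.2e3)
        + 2.5e2
    )
    hb = (
        _g(wl, 430, 15, 5.3e5)
        + _g(wl, 350, 30, 4.0e4)
        + _g(wl, 480, 45, 2.2e4)
        + _g(wl, 555, 17, 5.2e4)
        + _g(wl, 620, 45, 8.0e3)
        + _g(wl, 760, 28, 1.4e3)
        + np.where(wl > 600, 6.0e2, 1.0e3) * np.exp(-((wl - 600) / 260.0) ** 2)
        + 3.0e2
    )
    return pd.DataFrame(
        {"wavelength_nm": wl, "eps_hbo2": hbo2.round(3), "eps_hb": hb.round(3)}
    )


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "msimon" / "data"
    out.mkdir(parents=True, exist_ok=True)
    df = build_table()
    df.to_csv(out / "synthetic_hb_extinction.csv", index=False)
    print(f"wrote {out / 'synthetic_hb_extinction.csv'} ({len(df)} rows)")
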