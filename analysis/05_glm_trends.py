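#!/usr/bin/env python
"""Era-split Gamma-GLM trend fits of wall-type rates against time.

Fits sqrt-link Gamma GLMs of each wall type's origination and extinction
rates on epoch midpoint age, separately for the Palaeozoic and the combined
Mesozoic+Cenozoic, and writes coefficient summaries and +/-1 SE prediction
bands under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from foramdiv.rates import crossing_counts, foote_rates
from foramdiv.taxa_io import filter_benthic, read_genus_table
from foramdiv.timescale import load_timescale
from foramdiv.trends import InsufficientDataError, fit_rate_trend, predict_band

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ts = load_timescale()
    ds = filter_benthic(read_genus_table(OUT / "synthetic_genera.csv", ts))

    summaries, bands = [], []
    for group in ("calcareous", "agglutinated"):
        rs = foote_rates(crossing_counts(ds, group=group), ts)
        for era in ("Palaeozoic", "Mesozoic+Cenozoic"):
            for kind in ("p", "q"):
                try:
                    fit = fit_rate_trend(rs, ts, era=era, rate_kind=kind)
                except InsufficientDataError as exc:
                    print(f"skipped: {exc}")
                    continue
                summaries.append(fit.summary_row())
                star = " *" if fit.significant else ""
                print(
                    f"{era:18s} {fit.response_label:26s} slope {fit.slope:+.2e}/Ma "
                    f"(p={fit.p_slope:.3f}{star}, n={fit.n_points}, "
                    f"excluded={fit.excluded_points})"
                )
                band = predict_band(fit, np.linspace(fit.age_range[0], fit.age_range[1], 60))
                band.insert(0, "response", fit.response_label)
                band.insert(0, "era", era)
                bands.append(band)

    pd.DataFrame(summaries).to_csv(OUT / "glm_fits.csv", index=False, float_format="%.10g")
    pd.concat(bands, ignore_index=True).to_csv(
        OUT / "glm_bands.csv", index=False, float_format="%.10g"
    )
    print(f"wrote {OUT / 'glm_fits.csv'} and glm_bands.csv")


if __name__ == "__main__":
    main()
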