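# arcrange

Home-range-size analysis for GPS-collared female grizzly bears (*Ursus
arctos*) in low-heterogeneity Arctic landscapes — and for anyone who wants a
tested, reusable implementation of that workflow on their own telemetry.

Female home-range size is expected to reflect both reproductive status
(solitary, cubs-of-the-year, cubs ≥ 1 year) and the availability and spatial
configuration of seasonally preferred cover. `arcrange` implements the full
inference chain needed to test those hypotheses:

1. **Home ranges** — 95% fixed-kernel ranges from an isotropic bivariate
   normal kernel with the bandwidth *h* chosen by least-squares
   cross-validation (LSCV), plus multi-annual 100% minimum convex polygons
   (MCPs) and a ≥ 60% study-area inclusion filter.
2. **Seasons** — Ward's minimum-variance clustering of standardized
   bi-weekly cover-use profiles; the number of seasons is chosen from the
   Duda–Hart Je(2)/Je(1) index and the pseudo-*t*² statistic, then seasons
   are made temporally contiguous.
3. **Resource selection** — use–availability logistic regression with a
   per-bear random intercept (design III), water as the reference cover, an
   80:20 train:test split, and availability sampled at 1 point/km² inside
   each bear's multi-annual MCP. Each cover's coefficient β gives a relative
   selection index RSI = exp(|β|); covers with β > 0 and RSI ≥ 2 are
   reclassified as *highly selected*, water stays the reference, everything
   else is *matrix*. The reclassified map is validated on the held-out fixes
   with Manly selection ratios w_s = u_s / a_s and a Wald test of
   mean w_s = 1.
4. **Landscape metrics** — inside each annual kernel range: proportional
   amount of selected cover, landscape shape index LSI = 0.25·E/√A, edge
   density (m/ha), water LSI/edge, and Shannon–Wiener diversity
   H = −Σ pᵢ ln pᵢ.
5. **Model comparison** — candidate linear mixed models of log₁₀ range area
   (per-bear random intercept, ML), screened for collinearity
   (|Pearson r| ≥ 0.6, VIF > 10), ranked by AICc with Akaike weights
   wᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2), a confidence set of models whose weight is
   within 10% of the best, per-term importance weights, conditional model
   averaging, and a boundary-corrected likelihood-ratio test of the random
   effect.

No telemetry ships with the package. A first-class `synthetic_data` module
generates categorical landscapes (smoothed Gaussian random fields thresholded
at target class quantiles; ~35% water by default) and cover-biased correlated
random walks with programmed seasonal preferences, so every stage is testable
against known ground truth.

## Worked example

Recompute the model-selection arithmetic from a published final candidate
table of twelve AICc values:

```python
from arcrange import hr_models as hm
from arcrange.rsf import rsi_from_coefficient

aicc = [-74.01, -73.68, -72.11, -60.01, -45.74, -39.73,
        -30.19, -29.22, -27.76, 7.80, 16.23, 22.28]
terms = [("rs", "s1lsi"), ("s1lsi",), ("rs", "s1lsi", "wlsi")]  # top three

deltas, weights = hm.akaike_weights(aicc)
print([round(w, 2) for w in weights[:4]])   # [0.45, 0.38, 0.17, 0.0]

records = [hm.ModelRecord(terms=t, k=1 + len(t), logl=0.0, aicc=a, weight=float(w))
           for t, a, w in zip(terms + [("x",)] * 9, aicc, weights)]
conf = hm.confidence_set(records)           # 3 models within 10% of the best
imp = hm.importance_weights(conf)
print(round(imp["rs"], 2), round(imp["s1lsi"], 2))                  # 0.62 1.0
print(round(hm.plausibility_ratio(imp, "s1lsi", "rs"), 2))          # 1.61

print(rsi_from_coefficient(3.20), rsi_from_coefficient(-2.31))      # 24.5 10.1
```

The top model holds 45% of the Akaike weight; the spatial configuration of
season-1 selected cover (`s1lsi`, importance 1.00) is 1.61× more plausible a
correlate of range size than reproductive status (`rs`, importance 0.62). A
coefficient of 3.20 against the water reference is a 24.5-fold relative
selection index; −2.31 is a 10.1-fold avoidance.

End to end on synthetic data (10 animals, three programmed season regimes):

```bash
arcrange run-all --seed 11 --out out/
```

writes `out/report.json`, whose seasons stage reads `{"k": 3,
"breaks_week": [31, 39]}` — the clustering recovers the three programmed
seasons and their week-31/week-39 breaks — and whose RSF stage reports a
mean selection ratio above 1 with Wald P < 0.001 per season, i.e. the fitted
selection maps predict the held-out fixes. Per-stage artifacts (fix CSV,
landscape TIFF + legend, home-range and MCP GeoJSON, per-season effects
tables, metric and model-comparison CSVs) land next to it.

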