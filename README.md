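# dgdis — diagnostic disagreement between thermodilution and direct-Fick cardiac output

Precapillary pulmonary hypertension (PcPH) is defined haemodynamically as
mPAP > 20 mmHg, PAWP ≤ 15 mmHg and pulmonary vascular resistance
PVR = (mPAP − PAWP)/CO > 2 WU. The PVR — and hence the diagnosis — depends
on the cardiac output (CO), which is routinely measured by thermodilution
(TD) even though direct Fick (DF) is the reference method, and the
agreement between the two methods in this population is modest. For a
patient with mPAP > 20 mmHg and PAWP ≤ 15 mmHg, `dgdis` computes the
probability that using the direct-Fick CO instead of the thermodilution
value would flip the classification between PcPH and unclassified PH —
a number a catheterisation-lab clinician can use to decide whether a
direct-Fick measurement is worth adding.

## The model

The CO difference is taken to be normally distributed,

    X = CO_TD − CO_DF ~ N(μ, σ),     σ = LoA / 1.96,

where μ is the Bland–Altman bias and LoA the half-width of the limits of
agreement, and both CO values are constrained to a physiological interval
[a, b]. Writing TPG = mPAP − PAWP and r for the PVR threshold (2 WU), the
diagnosis under DF flips exactly when TPG/(CO_TD − X) crosses r, so the
disagreement probability is the truncated-normal conditional probability

    P(DgDis± | B) = P(DgDis± ∩ B) / P(B),
    P(B)          = P(CO_TD − b ≤ X ≤ CO_TD − a),
    P(DgDis+ ∩ B) = P(CO_TD − b ≤ X ≤ min(CO_TD − TPG/r, CO_TD − a)),
    P(DgDis− ∩ B) = P(max(CO_TD − TPG/r, CO_TD − b) ≤ X ≤ CO_TD − a),

where B is the event that the DF value is physiological, DgDis+ is a
false-positive PcPH diagnosis by TD (patient precapillary by TD) and
DgDis− a false negative (patient unclassified by TD). Defaults — μ = 0,
LoA = 2 L/min, [a, b] = [1.3, 10.2] L/min — summarise the published
resting TD-vs-DF agreement in PcPH; all are configurable. The resulting
probability maps to a clinical tier: < 10 % trust the TD diagnosis,
10–20 % consider measuring DF, > 20 % use DF.

## Worked example

A patient with mPAP 21 mmHg, PAWP 14 mmHg and CO_TD 4 L/min has
PVR_TD = 7/4 = 1.75 WU, so TD calls them unclassified PH:

```sh
$ dgdis prob --mpap 21 --pawp 14 --co-td 4
id,mpap,pawp,co_td,pvr_td,diagnosis,direction,dgdis_percent,tier
patient,21.0,14.0,4.0,1.75,unclassified_ph,minus,30.9,use_df
```

There is a 30.9 % probability that a direct-Fick measurement would
reclassify this patient as precapillary PH (a DgDis− flip) — firmly in
the "use direct Fick" tier. The same computation through the estimator
API:

```python
>>> from dgdis import DisagreementModel
>>> model = DisagreementModel().fit()            # default agreement
>>> model.predict_proba([[21, 14, 4]])[0, 1]     # mpap, pawp, co_td
0.30925389242354717
```

`DisagreementModel.fit` also accepts paired (CO_TD, CO_DF) measurements
and then estimates the bias and LoA itself by Bland–Altman analysis.
Other entry points: `dgdis table` (the worked-example tables, with
`--compare` showing deviations from the originally published values),
`dgdis simulate` / `dgdis ba` (fictive paired data and their Bland–Altman
summary), `dgdis map` (iso-probability and iso-PVR lines on the
TPG × CO_TD plane) and `dgdis verify` (Monte-Carlo cross-check).

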