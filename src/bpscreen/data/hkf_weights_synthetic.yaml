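# SYNTHETIC regression-weight table for the HKF-R 10 scoring machinery.
#
# The published instrument computes its score from the coefficients of a
# multiple regression model that is not reproduced here; those coefficients
# are NOT these. This file exists so that the weighted sum-product scorer,
# the five risk-category boundaries and every downstream pipeline stage can
# be exercised and tested. The weights are chosen only so that scores of a
# plausible cohort cover all five categories (boundaries -2.5, 8, 28, 37).
# Supply the real coefficient table for any substantive use.
intercept: -50.0
terms:
  - {item: 1,  weight: 1.5}
  - {item: 2,  weight: -0.8}
  - {item: 3,  weight: 0.9}
  - {item: 4,  weight: 0.7}
  - {item: 6,  weight: 0.6}
  - {item: 7,  weight: 0.5}
  - {item: 8,  weight: -0.5}
  - {item: 9,  weight: 0.55}
  - {item: 10, weight: 0.55}
  - {item: 11, weight: 0.55}
  - {item: 12, weight: 0.55}
  - {item: 13, weight: 0.55}
  - {item: 14, weight: 0.8}
  - {item: 15, weight: 0.8}
  - {item: 16, weight: 0.8}
  - {item: 17, weight: 0.8}
  - {item: 18, weight: 0.8}
  - {item: 19, weight: 0.65}
  - {item: 20, weight: 0.65}
  - {item: 21, weight: 0.65}
  - {item: 22, weight: 0.65}
  - {item: 23, weight: 0.65}
  - {item: 24, weight: 0.65}
  - {item: 25, weight: 0.65}
  - {item: 26, weight: 0.65}
  - {item: 27, weight: 0.65}
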