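"""Complexity of a trivariate cardiovascular-like subject.

Simulates a 256-beat HP/SAP/RESP system with a known coupling loop,
then computes the normalized complexity index (NCI) of each series with
the three estimators.  NCI is the fraction of the series' variance (MB,
LP) or information (CE) that the whole universe cannot explain: 0 means
fully predictable, 1 fully unpredictable.
"""

import cvcausal as cv

series, truth = cv.gen_trivariate(cv.cardio_like(256), seed=3)
bundle = cv.run_subject(cv.RunConfig(seed=0), series, subject_id="example")

print(f"{'method':<6} {'effect':<6} {'NCI':>6}  optimal order/dimension")
for rec in bundle["nci"]:
    print(f"{rec['method']:<6} {rec['effect']:<6} {rec['nci']:>6.3f}  {rec['optimal']}")

print()
print("Lower NCI = more of the series is explained by the universe.")
print("The linear (MB) and local-prediction (LP) indexes agree closely on")
print("this linear system; the conditional-entropy index runs higher at")
print("N=256 because each conditional sample holds only k=30 images.")
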