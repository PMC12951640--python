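"""Challenge-style evaluation of a segmentation against two raters.

Scores a simulated prediction against both rater masks of a phantom cohort
and prints the averaged per-subject metrics plus the weighted composite
Score = DSC/8 + PPV/8 + LTPR/4 + (1-LFPR)/4 + VC/4 (1.0 = perfect).
"""

from lesionseg.metrics import evaluate_against_raters, volume_correlation
from lesionseg.phantom import PhantomConfig, make_dataset

cohort, _ = make_dataset(6, PhantomConfig(), seed=3, val_fraction=0.0)

# use rater1 as the "prediction" and evaluate against both raters
preds = [s.rater1 for s in cohort]
vc_per_rater = [
    volume_correlation([(p, s.raters[r]) for p, s in zip(preds, cohort)]) for r in range(2)
]
print(f"cohort volume correlation per rater: {[round(v, 3) for v in vc_per_rater]}")

print(f"{'subject':>8} {'DSC':>6} {'PPV':>6} {'TPR':>6} {'LTPR':>6} {'LFPR':>6} {'Score':>6}")
for i, (pred, subj) in enumerate(zip(preds, cohort)):
    rep = evaluate_against_raters(pred, list(subj.raters), vc_per_rater)
    print(
        f"{i:>8} {rep.dsc:6.3f} {rep.ppv:6.3f} {rep.tpr:6.3f} "
        f"{rep.ltpr:6.3f} {rep.lfpr:6.3f} {rep.score:6.3f}"
    )
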