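"""Build the representative-sample train set from existing users.

One k-means centroid per gesture (seeded at the class mean) gives the
gesture templates; for every (user, gesture) pair the 30 features closest
to the template are kept.  With 9 existing users and 4 gestures this is
the 1,080 x 16 train set the online classifier starts from.
"""

import numpy as np

import synadapt as sa

cfg = sa.SynthConfig(users=10, gestures=4, channels=16, repetitions=6,
                     master_seed=0)
recordings = sa.generate_cohort(cfg)
existing, new_user = recordings[1:], recordings[0]

features = [
    f
    for i, rec in enumerate(existing)
    for f in sa.extract_features(rec, seed=100 + i)
]
print(f"feature pool from {len(existing)} existing users: "
      f"{len(features)} x {len(features[0].w)}")

trainset = sa.trainset_from_features(features, per_class=30)
print(f"representative train set: {trainset.n_train} x {trainset.m} "
      f"({len(existing)} users x {trainset.gesture_count} gestures x 30)")
print(f"initial weights: all {np.unique(trainset.weights)}")
for g, t in sorted(trainset.templates.items()):
    print(f"  template gesture {g}: dominant channel {int(np.argmax(t.mu))}")
print("The pool shrinks by "
      f"{len(features) / trainset.n_train:.1f}x while keeping one compact, "
      "template-centred prototype cloud per user and gesture.")
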