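# zspose

Attribute-based zero-shot and few-shot classification of human poses
from body-worn IMU sensors.

Adding a new target pose to a supervised recogniser normally means
collecting and labelling new sensor data.  `zspose` instead recognises
poses that have **no training recordings at all**: every pose is
described symbolically by the states of 14 body joints, per-joint CNN
estimators map raw IMU windows into that attribute space, and a
nearest-prototype rule assigns labels — with a distance that knows
*which joints matter for which pose*.  It is aimed at researchers
working on zero-/few-shot human activity recognition with wearables.

## Model

Joint states form an attribute vector a ∈ [0,1]^D (D = 33): simplex
slices from softmax heads for multi-state joints (head, shoulders,
hands, waist), scalars from sigmoid heads for one-degree-of-freedom
joints (elbows, wrists, hips, knees).  Class prototypes v(i) are data
means (seen classes) or expanded definition rows (unseen classes).  The
naive nearest-prototype distance

d(a, v) = ( Σ_d w_rc(d) · |a_d − v_d|^p )^(1/p),  w_rc = 0.5 (classification dims) / 1 (regression dims)

treats all joints as equally diagnostic.  The importance-weighted
distance masks, per candidate class i, the joints that class leaves
free:

d(a, v(i)) = 1/W_ai(i) · ( Σ_d w_ai(d,i) · w_rc(d) · |a_d − v_d(i)|^p )^(1/p) + λ / W_ai(i)

where w_ai(d,i) ∈ {0,1} is copied from a per-class, per-joint importance
table and W_ai(i) = Σ_j w′_ai(j,i) counts the class's diagnostic
joints; the λ term penalises classes defined by few joints.  Defaults
p = 1, λ = 0.1.  A squatting subject may hold elbows bent or straight —
the weighted metric ignores elbows *for squatting* while keeping them
for poses like arm folding.  See `docs/methods.md` for the full account.

The package ships the complete 22-pose fixture set (schema, pose
definitions, importance table, observed intra-class variation), a
seeded synthetic-data generator at attribute and signal level, numpy
implementations of the per-joint time-series CNNs, and the
leave-one-class-out ZSL / k-shot / random-importance evaluation
protocols, plus a `zspose` command-line interface.

## Worked example

```python
import zspose as z

schema = z.default_schema()          # 14 joints, D = 33
defs   = z.default_definitions()     # 22 symbolic pose rows
imp    = z.default_importance()      # per-class binary joint weights

mat, classes = z.expand_definition_table(defs, schema)
vec = dict(zip(classes, mat))

print(z.naive_distance(vec["Standing"], vec["Raising arm (L)"], schema))
print(z.naive_distance(vec["Standing"], vec["Sitting"], schema))
print(z.weighted_distance(vec["Squatting"],
                          z.ClassPrototype("Squatting", vec["Squatting"]),
                          imp.row("Squatting"), schema))

X, labels = z.generate_attribute_samples(defs, z.default_variation_spec(),
                                         n_per_class=60, seed=1)
from zspose.evaluation import loco_zsl_evaluate, EvalConfig
print(loco_zsl_evaluate(X, labels, defs, imp,  EvalConfig("weighted")).average_f)
print(loco_zsl_evaluate(X, labels, defs, None, EvalConfig("naive")).average_f)
```

prints

```
1.0
2.0
0.0125
0.9080309833210198
0.8845830872969788
```

Reading the numbers: standing and raising the left arm differ in one
shoulder state (one-hot L1 distance 2 halved by w_rc); standing and
sitting differ by 0.5 in both hips and both knees; a squatting sample
identical to its definition keeps only the penalty λ/W_ai = 0.1/8.  On
a corpus of 60 noisy samples per class with the observed intra-class
variation, the importance-weighted metric reaches a leave-one-class-out
average F-measure of 0.908 against 0.885 for the importance-free
baseline — the weighting absorbs exactly the variation the free joints
carry.

The same protocols run from the shell:

```sh
zspose simulate-attributes --n-per-class 60 --seed 1 --out samples.csv
zspose zsl-eval --samples samples.csv --metric weighted --out zsl.csv
zspose fewshot-eval --samples samples.csv --k 3 --out fs3.csv
zspose random-baseline --samples samples.csv --reps 100 --out rb.csv
```

and the signal-level path (`simulate-imu`, `train-estimators`,
`estimate`) covers recordings → CNN attribute estimates → evaluation.

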