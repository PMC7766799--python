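# leadtract

In-silico selection of the most effective deep-brain-stimulation (DBS)
contact for essential tremor, based on the overlap between each
contact's stimulation volume and the individual dentatorubrothalamic
tract (DRTT).

## The problem

Patients with medication-refractory essential tremor are treated with
DBS of the thalamic VIM / posterior subthalamic area.  Modern
*directional* leads carry eight contacts — a ventral ring, two levels
of three 120°-spaced segments, and a dorsal ring — and finding the
best one by monopolar review (testing every contact clinically) is
slow and exhausting for the patient.  Because tremor suppression is
mediated by the cerebello-thalamo-cortical pathway, a contact's
effectiveness tracks how much of the DRTT its stimulation field
reaches.  `leadtract` implements that idea as a reusable pipeline for
clinician-researchers working with directional thalamic leads:

1. **Field / VTA model** (`field_vta`) — each contact is a set of
   weighted point current sources in a homogeneous isotropic medium;
   the field magnitude at distance *r* from a source carrying current
   *I* is |E| = *I* / (4πσ*r*²), and the volume of tissue activated
   (VTA) is the set of voxels where |E| ≥ E_t.  Defaults: σ = 0.1 S/m,
   E_t = 0.2 V/mm, 2 mA test amplitude (130 Hz, 60 µs carried as
   metadata).  For a single point source at 2 mA this gives an
   activation sphere of radius √(I/(4πσE_t)) ≈ 2.82 mm (≈ 94 mm³),
   which the implementation reproduces to < 0.1% on a 0.2 mm grid.
2. **Overlap score** (`tract_overlap`) — with a track probability map
   *p* (normalized streamline visitation frequencies in [0, 1]) the
   score of a contact is Σ_{v ∈ VTA} p(v) · voxel-volume, a
   probability-weighted overlap volume in mm³.
3. **Ranking & concordance** (`selection_eval`) — contacts are ranked
   hemisphere-wise by overlap (competition ranking) and compared with
   per-contact tremor improvement; top-1/top-2 hit rates and a
   directional-only rate (chance level 100/6 ≈ 16.7%) summarize how
   often the overlap ranking finds the clinically best contact.
4. **Mixed model** (`mixed_model`) — improvement ~ β₀ + β₁·overlap
   with a random intercept per lead (REML), decomposed into marginal
   and conditional R² after Nakagawa & Schielzeth.
5. **Synthetic cohort** (`synthetic_data`) — tract maps (Gaussian
   tube), lead poses and integer tremor-rating-scale responses with
   the statistical structure above, so the full pipeline is testable
   without patient data.

Clinical inputs are plain files: tract maps as NIfTI-1, lead poses
(tip, shaft direction, rotation) and tremor scores as CSV.

## Worked example

```sh
leadtract simulate --out cohort --seed 1            # 7 patients, 14 leads
leadtract score cohort                              # VTAs + overlaps at 2 mA
leadtract evaluate cohort/overlaps.csv cohort/trs_scores.csv --out report
```

prints (seed 1):

```
112 contact scores written to cohort/overlaps.csv
top-1 57.1% (8/14), top-2 71.4%, directional top-1 64.3%
R2 marginal 0.597, conditional 0.807, slope p = 6.41e-16
```

meaning: on this synthetic cohort the highest-overlap contact was
(among) the clinically best in 8 of 14 hemispheres, the top two
overlap ranks covered the best contact in 71.4%, and tract overlap
alone explained ~60% of the outcome variance (≈81% together with the
per-lead random intercepts).  `report/report.json` holds the full
per-hemisphere rankings plus a ranking bar figure and the fitted
mixed-model figure.

The same stages are available as library calls
(`leadtract.pipeline.run_simulate / run_score / run_evaluate`) for
scripted use on real cohort directories.

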