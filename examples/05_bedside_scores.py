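"""The study's defined bedside scores on small worked inputs."""

from pigtrial.scores import (
    BloodCounts, GridCount, aggregate_eeg, classify_background,
    ramification_index, region_ri, siri,
)

# microglial ramification index: (process-gridline intersections)^2 / somata
g = GridCount(intersections=12, somata=3, field_id="f1", region="CAUD")
print(f"one field: {g.intersections} intersections, {g.somata} somata "
      f"-> RI = {ramification_index(g):.1f}  (high = ramified/resting microglia)")

fields = [GridCount(12, 3), GridCount(9, 2), GridCount(15, 4),
          GridCount(7, 2), GridCount(11, 3), GridCount(10, 2)]
mean_ri, n = region_ri(fields, "CAUD")
print(f"caudate mean over {n} fields: RI = {mean_ri:.1f}")

# systemic inflammation response index from a full blood count
b = BloodCounts(neutrophils=8.2, monocytes=1.1, lymphocytes=3.4, timepoint_h=24)
print(f"\nSIRI at 24 h = {siri(b):.2f}  (neutrophils x monocytes / lymphocytes; "
      "lower after treatment suggests reduced systemic inflammation)")

# aEEG: classify one hour from its voltage margins, then aggregate a day
score = classify_background(lower_margin=3.0, upper_margin=15.0)
print(f"\ntrace with margins 3-15 uV -> background score {score} (discontinuous)")
hourly = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 3, 3, 2, 3, 3, 3, 4, 3, 4, 4, 4, 4, 4, 4]
epochs = aggregate_eeg(hourly, epoch_h=6)
print("24 h of hourly scores aggregated to 6-h epochs:")
print(epochs[["epoch", "mean_score", "n_hours"]].to_string(index=False))
print("  [rising epoch means = background recovery after the insult]")
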