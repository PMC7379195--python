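"""Generate one block of each sequence type and inspect its regularities.

The oddball block embeds a rare 500-Hz deviant (1/8 of trials) in a
550-Hz standard stream; the cascade block cycles the frequency ladder up
and down; the no-repetition block shuffles the same tones under a
no-adjacent-repeat constraint. The printed statistics verify the design
rules: deviant rarity, zero adjacent repeats in both control blocks, and
identical tone proportions across the two control blocks.
"""

from mmnlab import SequenceSpec, generate_sequence, sequence_stats

spec = SequenceSpec(seed=1)

for condition in ("oddball", "cascade", "norep"):
    seq = generate_sequence(condition, spec)
    stats = sequence_stats(seq)
    first = [int(e.frequency_hz) for e in seq.analyzed_events[:10]]
    print(f"\n{condition}: {len(seq)} events "
          f"({len(seq.analyzed_events)} analyzed)")
    print(f"  first analyzed tones (Hz): {first}")
    print(f"  tone proportions: { {int(f): round(p, 3) for f, p in stats.proportions.items()} }")
    print(f"  adjacent repeats (incl. warm-up junction): {stats.n_adjacent_repeats}")
    if stats.gap_histogram:
        print(f"  interdeviant-gap histogram: {stats.gap_histogram}")
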