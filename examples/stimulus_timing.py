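"""Build an SQM sequence and inspect its timing and geometry.

Every line lasts 20 ms; the first inter-stimulus interval is 30 ms and
all later ones 20 ms, so flanking frame n starts at 50 + 40*(n-1) ms.
"""

from sqmsim import build_sequence, frame_onset, get_condition, sequence_to_table

for frame in (1, 5, 7, 8, 11, 12, 14):
    print(f"frame {frame:2d} starts at {frame_onset(frame):3d} ms")

seq = build_sequence(get_condition("V-AV8"))
print(f"\ncondition V-AV8: {len(seq.elements)} line elements, "
      f"total duration {seq.duration_ms} ms")

table = sequence_to_table(seq)
offset_rows = table[table.offset_sign != 0]
print("\noffset elements (the central pro-vernier and the frame-8 "
      "anti-vernier on the attended left stream):")
print(offset_rows.to_string(index=False))
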