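# Drift-segment assignment rules, per inflection-order group.
#
# Segments are numbered 1-3 and join consecutive subsurface inflection
# points (segment i: IFP_i -> IFP_{i+1}); the descent (start -> IFP1) and
# final ascent (IFP4 -> end) are never drift segments.  Rules are evaluated
# in order; the first predicate that fires assigns the segment, otherwise
# the group's fallback applies.  Predicates are expressions over the
# dive-shape variables (see driftdive.shape_features).
#
# The source table for these rules is typeset with ambiguous cell
# boundaries in some rows; cells whose column placement had to be
# reconstructed from the row structure are marked "reconstructed" below.
# Edit this file (or pass your own) to use a verified transcription.

whitelist:
  - "2.1.3.4"
  - "2.1.4.3"
  - "2.4.1.3"
  - "3.1.2.4"
  - "3.1.4.2"
  - "3.2.1.4"
  - "3.4.1.2"
  - "4.2.1.3"

groups:
  "2.1.3.4":
    rules:
      - {when: "mdepthbias > 0", segment: 1}
      - {when: "mdepthbias < 0", segment: 2}
    fallback: 1
  "2.1.4.3":
    rules:
      - {when: "ps1 > 0.25", segment: 1}
      - {when: "ps1 <= 0.25 and (1.1 * ps2) >= ps3", segment: 2}
      - {when: "ps1 <= 0.25 and (1.1 * ps2) < ps3", segment: 3}
    fallback: 1
  "2.4.1.3":  # reconstructed: segment-1 cell spans two alternatives
    rules:
      - {when: "(mdepthbias < 0 and ps1 > ps3) or (mdepthbias > 0 and ps1 <= ps2)", segment: 1}
      - {when: "mdepthbias < 0 and ps1 <= ps2", segment: 2}
      - {when: "mdepthbias > 0 and ps1 > ps2", segment: 3}
    fallback: 1
  "3.1.2.4":  # reconstructed: four predicates over three columns
    rules:
      - {when: "avratio < 0", segment: 1}
      - {when: "avratio > 0 or (ps1 < 0.25 and s < 0 and t > 0)", segment: 2}
      - {when: "ps1 < 0.25 and s > 0 and t < 0", segment: 3}
    fallback: 1
  "3.1.4.2":  # reconstructed: duplicated tokens dropped
    rules:
      - {when: "ps1 > 0.25", segment: 1}
      - {when: "ps1 <= 0.25 and s < 0 and hp2 > hp3", segment: 2}
      - {when: "ps1 <= 0.25 and s < 0 and hp2 < hp3", segment: 3}
    fallback: 1
  "3.2.1.4":
    # All dives in this group drift along segment 2; no criteria needed.
    rules: []
    fallback: 2
  "3.4.1.2":
    rules:
      - {when: "mdepthbias > 0 and ps1 > ps2", segment: 1}
      - {when: "mdepthbias > 0 and ps1 < ps2", segment: 2}
      - {when: "mdepthbias < 0", segment: 3}
    fallback: 2
  "4.2.1.3":
    # reconstructed: under this order the 4th time-sorted point is the
    # deepest, so segment 1 (descent limb to IFP1) cannot be the passive
    # phase; the two mdepthbias branches are assigned to segments 2/3.
    rules:
      - {when: "mdepthbias >= 0", segment: 2}
      - {when: "mdepthbias < 0", segment: 3}
    fallback: 2
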