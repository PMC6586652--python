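# Default per-group, per-sign threshold criteria for candidate drift dives.
#
# Rules matching a candidate's (group, sign) are applied in `order`; the
# first failing rule rejects the dive.  `op` is a strict one-sided bound
# ("<" or ">"); intervals are written as two sequential one-sided rules
# (the published bracketed pairs are open intervals).  `sign` is
# "negative", "positive" or "both".
#
# Transcription note: the source table types 15 (group, sign) columns whose
# per-row cell alignment is not recoverable from the extracted text.  This
# default file therefore ships only the rows whose attribution is
# determinate:
#   * d1 < 0.8 for every group (the bound the prose reports across all
#     groups), replaced by d2 < 0.8 for group 3.2.1.4 whose drift segment
#     is always segment 2;
#   * d4 < 0.8 for every group except 4.2.1.3, where the 4th time-sorted
#     point is the deepest (d4 = 1 by construction);
#   * mrratio, t4 and ps1 rows with the loosest printed value applied to
#     the columns where the criterion is structurally meaningful.
# Rows t1, sratio, mdepthr, sdd, ps2, ps3, r1, r4, mdepthbias and meand are
# computed as variables but omitted here pending a verified transcription;
# add them to a copy of this file to use them.

rules:
  # --- d1 / d2 -----------------------------------------------------------
  - {group: "2.1.3.4", sign: both, criterion: d1, op: "<", value: 0.8, order: 1}
  - {group: "2.1.4.3", sign: both, criterion: d1, op: "<", value: 0.8, order: 1}
  - {group: "2.4.1.3", sign: both, criterion: d1, op: "<", value: 0.8, order: 1}
  - {group: "3.1.2.4", sign: both, criterion: d1, op: "<", value: 0.8, order: 1}
  - {group: "3.1.4.2", sign: both, criterion: d1, op: "<", value: 0.8, order: 1}
  - {group: "3.2.1.4", sign: both, criterion: d2, op: "<", value: 0.8, order: 1}
  - {group: "3.4.1.2", sign: both, criterion: d1, op: "<", value: 0.8, order: 1}
  - {group: "4.2.1.3", sign: both, criterion: d1, op: "<", value: 0.8, order: 1}
  # --- d4 ----------------------------------------------------------------
  - {group: "2.1.3.4", sign: both, criterion: d4, op: "<", value: 0.8, order: 2}
  - {group: "2.1.4.3", sign: both, criterion: d4, op: "<", value: 0.8, order: 2}
  - {group: "2.4.1.3", sign: both, criterion: d4, op: "<", value: 0.8, order: 2}
  - {group: "3.1.2.4", sign: both, criterion: d4, op: "<", value: 0.8, order: 2}
  - {group: "3.1.4.2", sign: both, criterion: d4, op: "<", value: 0.8, order: 2}
  - {group: "3.2.1.4", sign: both, criterion: d4, op: "<", value: 0.8, order: 2}
  - {group: "3.4.1.2", sign: both, criterion: d4, op: "<", value: 0.8, order: 2}
  # --- mrratio -----------------------------------------------------------
  - {group: "2.1.3.4", sign: both, criterion: mrratio, op: "<", value: 0.3, order: 3}
  - {group: "2.1.4.3", sign: both, criterion: mrratio, op: "<", value: 0.3, order: 3}
  - {group: "2.4.1.3", sign: both, criterion: mrratio, op: "<", value: 0.3, order: 3}
  - {group: "3.1.2.4", sign: both, criterion: mrratio, op: "<", value: 0.3, order: 3}
  - {group: "3.1.4.2", sign: both, criterion: mrratio, op: "<", value: 0.3, order: 3}
  - {group: "3.2.1.4", sign: both, criterion: mrratio, op: "<", value: 0.3, order: 3}
  - {group: "3.4.1.2", sign: both, criterion: mrratio, op: "<", value: 0.3, order: 3}
  - {group: "4.2.1.3", sign: both, criterion: mrratio, op: "<", value: 0.3, order: 3}
  # --- ps1 (groups whose drift segment is segment 1, negative dives) -----
  - {group: "2.1.3.4", sign: negative, criterion: ps1, op: ">", value: 0.4, order: 4}
  - {group: "2.1.4.3", sign: negative, criterion: ps1, op: ">", value: 0.4, order: 4}
  # --- t4 ----------------------------------------------------------------
  - {group: "2.1.3.4", sign: negative, criterion: t4, op: ">", value: 0.8, order: 5}
  - {group: "2.1.4.3", sign: negative, criterion: t4, op: ">", value: 0.8, order: 5}
  - {group: "2.4.1.3", sign: negative, criterion: t4, op: ">", value: 0.8, order: 5}
  - {group: "3.1.2.4", sign: negative, criterion: t4, op: ">", value: 0.8, order: 5}
  - {group: "3.1.4.2", sign: negative, criterion: t4, op: ">", value: 0.8, order: 5}
  - {group: "3.2.1.4", sign: negative, criterion: t4, op: ">", value: 0.8, order: 5}
  - {group: "3.4.1.2", sign: negative, criterion: t4, op: ">", value: 0.8, order: 5}
  - {group: "4.2.1.3", sign: negative, criterion: t4, op: ">", value: 0.8, order: 5}
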