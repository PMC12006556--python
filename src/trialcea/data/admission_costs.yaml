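# Hospitalisation costs per HRG-costed admission category: cost per episode,
# average length of stay (days) and cost per excess bed day. 2015/16 national
# reference costs uprated to 2021/22 (uprating applied in these values; the
# engine does no inflation arithmetic). Post-amputation rehabilitation is a
# separate one-off cost attached to each amputation admission.
price_year: "2021/22"
post_amputation_cost: 529.0
categories:
  major_amputation:
    cost_per_episode: 11723.0
    average_length_of_stay: 19.0
    cost_per_excess_bed_day: 313.0
  minor_amputation:
    cost_per_episode: 5385.0
    average_length_of_stay: 9.0
    cost_per_excess_bed_day: 328.0
  revascularisation:
    cost_per_episode: 8329.0
    average_length_of_stay: 7.0
    cost_per_excess_bed_day: 368.0
  osteotomy:
    cost_per_episode: 2506.0
    average_length_of_stay: 2.0
    cost_per_excess_bed_day: 373.0
  surgical_debridement:
    cost_per_episode: 817.0
    average_length_of_stay: 1.0
    cost_per_excess_bed_day: 0.0
  arthroplasty:
    cost_per_episode: 3969.0
    average_length_of_stay: 2.0
    cost_per_excess_bed_day: 389.0
  osteomyelitis:
    cost_per_episode: 3905.0
    average_length_of_stay: 8.0
    cost_per_excess_bed_day: 314.0
  frame_removal:
    cost_per_episode: 2034.0
    average_length_of_stay: 2.0
    cost_per_excess_bed_day: 357.0
  gastrocnemius_release:
    cost_per_episode: 2034.0
    average_length_of_stay: 2.0
    cost_per_excess_bed_day: 357.0
  cellulitis:
    cost_per_episode: 1791.0
    average_length_of_stay: 6.0
    cost_per_excess_bed_day: 1791.0
  other:
    cost_per_episode: 2637.0
    average_length_of_stay: 7.0
    cost_per_excess_bed_day: 295.0
# Categories that receive the post-amputation rehabilitation add-on.
amputation_categories: [major_amputation, minor_amputation]
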