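{
  "name": "PBI-AR-K",
  "scale_labels": ["not at all", "a little", "moderately", "quite", "very"],
  "not_apply_label": "does/did not apply to me",
  "items": [
    {"id": 1, "need_text": "no longer have to sneeze", "benefit_text": "no longer have to sneeze"},
    {"id": 2, "need_text": "no longer have a runny or stuffy nose", "benefit_text": "no longer have a runny or stuffy nose"},
    {"id": 3, "need_text": "be able to breathe through your nose freely", "benefit_text": "be able to breathe through my nose freely"},
    {"id": 4, "need_text": "feel less tired or groggy", "benefit_text": "feel less tired or groggy"},
    {"id": 5, "need_text": "be able to stay outdoors without symptoms", "benefit_text": "be able to stay outdoors without symptoms"},
    {"id": 6, "need_text": "have an easily applicable treatment", "benefit_text": "have an easily applicable treatment"},
    {"id": 7, "need_text": "not have itching eyes, nose or throat anymore", "benefit_text": "not have itching eyes, nose or throat anymore"},
    {"id": 8, "need_text": "not have burning or watery eyes anymore", "benefit_text": "not have burning or watery eyes anymore"},
    {"id": 9, "need_text": "no longer have hay fever symptoms", "benefit_text": "no longer have hay fever symptoms"},
    {"id": 10, "need_text": "be able to sleep better", "benefit_text": "be able to sleep better"},
    {"id": 11, "need_text": "need less time for treatment", "benefit_text": "need less time for treatment"},
    {"id": 12, "need_text": "feel well even with having hay fever", "benefit_text": "feel well even with having hay fever"},
    {"id": 13, "need_text": "be able to do anything you want in your free time even while having hay fever", "benefit_text": "be able to do anything I want in my free time even while having hay fever"},
    {"id": 14, "need_text": "feel more comfortable being around other people", "benefit_text": "feel more comfortable being around other people"},
    {"id": 15, "need_text": "be focused at school", "benefit_text": "be focused at school"},
    {"id": 16, "need_text": "not be excluded by others", "benefit_text": "not be excluded by others"},
    {"id": 17, "need_text": "not to have to go to the doctor so often", "benefit_text": "not to have to go to the doctor so often"},
    {"id": 18, "need_text": "have a comfortable treatment", "benefit_text": "have a comfortable treatment"},
    {"id": 19, "need_text": "have fewer side effects", "benefit_text": "have fewer side effects"}
  ]
}
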