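{
  "acidic_pocket": ["D237", "E242", "D347"],
  "thumb_base": ["K380"],
  "central_vestibule": ["E413", "E375", "R371"],
  "side_cavity": ["V414", "N416", "I307"]
}
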