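# Synthetic English given/surname list authored for this package
# (generator input; not drawn from any published benchmark).
abigail
alexander
anderson
bennett
bradford
campbell
caroline
charlotte
christopher
daniels
dominic
eleanor
elizabeth
fitzgerald
franklin
gabriella
gardner
harrington
harrison
isabella
jefferson
jonathan
katherine
lancaster
lawrence
margaret
marshall
matthews
mitchell
montgomery
nathaniel
nicholas
oliveira
patterson
pemberton
phillips
prescott
quentin
reynolds
richardson
roberts
samantha
sebastian
sheffield
stanton
sullivan
theodore
thompson
underwood
valentine
victoria
wallace
whitfield
williams
winchester
zachary
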