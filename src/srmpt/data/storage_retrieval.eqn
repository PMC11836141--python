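# Storage-retrieval model for a recognition + cued-recall test of
# 20 targets and 20 distractors.
# Parameters: s  = target storage
#             r1 = target retrieval during recognition
#             g  = guessing "old" during recognition
#             r2 = target retrieval during cued recall
#             d  = distractor detection (identified via d := s*r1)
11
target Rn+Rc+ s*r1*r2
target Rn+Rc- s*r1*(1-r2)
target Rn+Rc+ s*(1-r1)*g*r2
target Rn+Rc- s*(1-r1)*g*(1-r2)
target Rn-Rc+ s*(1-r1)*(1-g)*r2
target Rn-Rc- s*(1-r1)*(1-g)*(1-r2)
target Rn+Rc- (1-s)*g
target Rn-Rc- (1-s)*(1-g)
distractor D+ d
distractor D+ (1-d)*(1-g)
distractor D- (1-d)*g
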