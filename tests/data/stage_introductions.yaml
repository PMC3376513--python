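# Golden copies of the five stage-of-change introduction texts; the shipped
# message library must reproduce these verbatim.
precontemplation: "It seems that you are not reaching the goal of 10,000 steps a day. That's a pity because being active has several health advantages, in both the short and the long term. People can experience these benefits when they are being physically active on a regular basis. The following tips could help people who want to be more active..."
contemplation: "It seems that you are not reaching the goal of 10,000 steps a day, but are planning to become more active at some point in the future. That's good because being active has several health advantages, in both the short and the long term. You could experience these benefits when you are being physically active on a regular basis. When you decide the time has come to take more steps, the following tips and suggestions will certainly be helpful..."
preparation: "You are intending to take more steps than you are taking now, and you want to reach this goal within 1 month. This is a good idea, as you are currently not reaching the goal of 10,000 steps a day which is needed to achieve health benefits. The following tips should help you to realize your good intentions..."
action: "Because you are already reaching the 10,000 steps goal, it doesn't seem necessary to overload you with tips to take even more steps. After all, you are doing well! Still, we want to give you some tips, which may be helpful in times when it is hard to keep up your high level of physical activity..."
maintenance: "Because your step level is high and you have been able to maintain this for quite a while, it seems unnecessary to give you tips to step more. They would probably not be very helpful. However, we want to emphasize that you are among the few Flemish people who are very active, and that's really good! Carry on being this active!"
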