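id,parent_id,level,weight,text
x1,,1,0.346,Professional quality
x11,x1,2,0.465,Communication skills
x111,x11,3,0.2,I can communicate well with the residents in dialect (for example in Guangdong province: Cantonese).
x112,x11,3,0.396,"I can assist the unit in the documentation and publicity work (such as the writing of the official account of the unit, propaganda and education documents, etc.)."
x113,x11,3,0.404,"At work, I can express academic ideas accurately, scientifically and rigorously, and exchange research results."
x12,x1,2,0.035,Social mobilization
x121,x12,3,0.286,"I am willing to have the initiative to understand the public health situation at the global, national, regional and community levels."
x122,x12,3,0.377,I would like to find community partners to carry out actions to promote the health of the residents.
x123,x12,3,0.337,I will pay close attention to current public health policies and seek opportunities to participate in activities that improve them.
x13,x1,2,0.185,Teamwork
x131,x13,3,0.275,"When performing tasks, I prefer team tasks where I can work with others."
x132,x13,3,0.725,"When carrying out emergency rescue tasks with the team, I will actively learn task-related information and actively share with members."
x14,x1,2,0.315,Organization and coordination skills
x141,x14,3,0.512,"During public health operations, I can quickly adjust myself to align my work status with the organization's activities."
x142,x14,3,0.488,I can encourage others to participate in action so as to promote internal collaboration.
x2,,1,0.614,Psychological capital
x21,x2,2,0.039,Optimism
x211,x21,3,0.275,I always see the bright side of things in my work.
x212,x21,3,0.259,I am optimistic about what will happen to my job in the future.
x213,x21,3,0.466,"In the face of public health events such as the COVID-19 pandemic, I always believe that 'there is a light at the end of the tunnel, do not be pessimistic.'"
x22,x2,2,0.198,Toughness
x221,x22,3,0.22,I believe I can work through any challenge I have at work.
x222,x22,3,0.254,I can do it on my own if I have to do hard work alone.
x223,x22,3,0.063,I usually take stress at work in stride.
x224,x22,3,0.23,"Even in the face of public health outbreaks, I am able to survive difficult times at work."
x225,x22,3,0.234,"In my current job, I feel like I can juggle many things at once."
x23,x2,2,0.318,Hope
x231,x23,3,0.313,"If I find myself stuck at work, I can think of many ways to get out of it."
x232,x23,3,0.097,"At present, I am full of energy to complete my work goals."
x233,x23,3,0.137,There are many solutions to any problem.
x234,x23,3,0.1,At the moment I am quite satisfied with what I have achieved in my work.
x235,x23,3,0.192,I can think of a number of ways to achieve my current workday goals.
x236,x23,3,0.161,"At the moment, I am achieving the work goals I set for myself."
x24,x2,2,0.445,Effectiveness
x241,x24,3,0.163,I believe I can analyze long-term problems and find solutions.
x242,x24,3,0.065,"In meetings, I am confident in stating things that are within the scope of my job."
x243,x24,3,0.184,I think I can improve the general well-being in the community which I work for.
x244,x24,3,0.137,"Within the scope of my job, I believe I can help set goals/objectives."
x245,x24,3,0.177,I believe in my ability to connect with people outside my working department to solve some related problems.
x246,x24,3,0.273,"If I were in the scene of a public health emergency, I believe I would be able to calmly analyze the situation and work on the front lines as soon as possible."
x3,,1,0.04,Emergency attitude
x31,x3,2,0.277,Disaster relief expectation
x311,x31,3,0.277,"If I have chance, I am willing to participate in the rescue work of public health emergencies."
x312,x31,3,0.218,"If I have chance, I am willing to assist in the disinfection of the epidemic area."
x313,x31,3,0.235,"During the public health emergency, I would be willing to receive psychological training to provide the psychological care and interventions that patients or community residents need."
x314,x31,3,0.269,"As a grass-roots medical worker, if I realize that there is a crisis of public health events such as infectious diseases, I will do all in my power to send a protective warning to the outside world."
x32,x3,2,0.191,Trained attitude
x321,x32,3,0.197,I am willing to learn more about public health emergencies.
x322,x32,3,0.259,It is necessary to carry out public health emergency related courses and training.
x323,x32,3,0.246,It is necessary to carry out emergency drills for public health emergencies.
x324,x32,3,0.297,It is important to master the basic knowledge of public health emergencies.
x33,x3,2,0.04,Mental reaction
x331,x33,3,0.533,I am terrified of a public health emergency.
x332,x33,3,0.467,Performing tasks related to public health emergencies such as daily epidemic prevention will make me feel stressed.
x34,x3,2,0.363,Awareness of prevention
x341,x34,3,0.256,"It is necessary to equip the household with emergency medicine kit (containing disinfectant, mask, anti-inflammatory drugs, anti-allergic drugs and other items), fire extinguisher and other basic emergency materials."
x342,x34,3,0.336,I am willing to assist community residents to carry out preventive vaccination and preventive medication.
x343,x34,3,0.409,I am willing to actively communicate with community residents and carry out health education on public health emergencies.
x35,x3,2,0.129,Self-evaluation
x351,x35,3,0.356,I am familiar with public health emergencies.
x352,x35,3,0.299,I will pay attention to the epidemic situation of local infectious diseases actively.
x353,x35,3,0.345,I will follow the World Health Organization's reports on various public health emergencies.
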